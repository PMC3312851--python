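"""Foot-to-foot onset detection on velocity and pressure waveforms.

The systolic wave-front "foot" is the reference landmark of the foot-to-foot
transit-time method, chosen because it is minimally disturbed by reflected
waves.  Two detectors are provided, matching how each signal is analysed in
practice:

* velocity curves: intersection of a horizontal line modeling the constant
  diastolic flow with the regression line through the systolic upslope
  samples lying within 20-80% of the total range (``detect_onset_velocity``);
* pressure curves: time of the minimal pressure prior to the systolic
  upslope (``detect_onset_pressure``).

Per-cycle onsets from a multi-cycle recording are combined with
``aggregate_onsets`` (median by default) to average out respiration-induced
beat-to-beat variation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AggregationError,
    InsufficientSamplesError,
    NonPhysicalSlopeError,
    NoUpslopeError,
)
from .waveforms import OnsetEstimate, SampledWaveform

__all__ = [
    "detect_onset_velocity",
    "detect_onset_pressure",
    "aggregate_onsets",
]

#: Range below this value is treated as numerically zero.
_ATOL = 1e-12


def _cyclic_prepeak(values: np.ndarray, times: np.ndarray, pk: int, rr: float):
    """Samples ordered cyclically to end at the peak, times unwrapped.

    Samples after the peak belong to the preceding (wrapped) part of the
    cycle and get their time reduced by one RR so the sequence is strictly
    increasing in time up to the peak.
    """
    n = values.size
    order = np.concatenate([np.arange(pk + 1, n), np.arange(0, pk + 1)])
    vv = values[order]
    tt = np.where(order > pk, times[order] - rr, times[order])
    return vv, tt


def detect_onset_velocity(
    cycle: SampledWaveform,
    *,
    band: tuple[float, float] = (0.2, 0.8),
    noise_floor_frac: float = 0.05,
    baseline_window_frac: float = 0.2,
) -> OnsetEstimate:
    """Detect the systolic foot of a single-cycle velocity waveform.

    The upslope line is a least-squares fit over the rising-limb samples
    whose value lies within ``band`` (default 20-80%) of the total range
    R = v_peak - v_trough, where the trough is the minimum on the limb
    preceding the peak (cyclic).  The first crossings of the two band
    thresholds are located by linear interpolation and included as anchor
    points of the fit, so the fit is well-posed even at CMR temporal
    resolution (~35 phases/cycle) where the band holds only 2-3 raw samples.
    The diastolic baseline is the median over the cyclic window covering the
    final 20% of the RR interval preceding the pre-systolic trough, the
    trough being located as the last pre-peak sample at or below the lower
    band threshold (the sample adjacent to the upstroke; anchoring on the
    raw argmin would let a noise dip anywhere in diastole drag the baseline
    window onto the systolic decay).  The onset is the (real-valued)
    intersection of the baseline with the upslope line.

    Raises
    ------
    NoUpslopeError
        Range below ``noise_floor_frac`` of the absolute maximum (flat curve).
    InsufficientSamplesError
        Fewer than 3 fit points (no raw sample strictly inside the band).
    NonPhysicalSlopeError
        Non-positive fitted upslope.
    """
    v = cycle.values
    n = v.size
    if n < 4:
        raise InsufficientSamplesError("cycle too short for onset detection")
    rr = cycle.rr_s
    times = cycle.times
    pk = int(np.argmax(v))  # earliest index on ties
    absmax = float(np.max(np.abs(v)))
    vv, tt = _cyclic_prepeak(v, times, pk, rr)
    v_tr = float(np.min(vv[:-1]))
    rng = float(v[pk] - v_tr)
    if absmax <= _ATOL or rng <= _ATOL or rng < noise_floor_frac * absmax:
        raise NoUpslopeError("velocity range below noise floor; no systolic wave")

    lo = v_tr + band[0] * rng
    hi = v_tr + band[1] * rng

    # rising limb anchored at the last pre-peak sample at/below the lower
    # band threshold (= the pre-systolic trough side of the upstroke)
    below = np.nonzero(vv[:-1] <= lo)[0]
    tr_j = int(below[-1])
    seg_v = vv[tr_j:]
    seg_t = tt[tr_j:]

    i_lo = 0
    hi_idx = np.nonzero(seg_v[i_lo + 1 :] >= hi)[0]
    i_hi = i_lo + 1 + int(hi_idx[0])
    n_interior = i_hi - 1 - i_lo
    if n_interior < 1:
        raise InsufficientSamplesError(
            "fewer than 3 fit points in the 20-80% upslope band"
        )

    def _cross(i: int, level: float) -> float:
        dv = seg_v[i + 1] - seg_v[i]
        frac = 0.5 if dv == 0 else (level - seg_v[i]) / dv
        return float(seg_t[i] + frac * (seg_t[i + 1] - seg_t[i]))

    t_lo = _cross(i_lo, lo)
    t_hi = _cross(i_hi - 1, hi)
    ts_fit = np.concatenate([[t_lo], seg_t[i_lo + 1 : i_hi], [t_hi]])
    vs_fit = np.concatenate([[lo], seg_v[i_lo + 1 : i_hi], [hi]])
    slope, intercept = np.polyfit(ts_fit, vs_fit, 1)
    if slope <= 0:
        raise NonPhysicalSlopeError("fitted systolic upslope is not positive")

    # diastolic baseline: median over the final 20% of RR preceding the trough
    t_tr = float(seg_t[0])
    delta = np.mod(t_tr - times, rr)
    mask = (delta > 0) & (delta <= baseline_window_frac * rr)
    baseline = float(np.median(v[mask])) if np.any(mask) else v_tr

    onset = float((baseline - intercept) / slope)
    t_start = cycle.start_time_s
    valid = (t_start - 0.5 * rr) <= onset <= (t_start + rr)
    return OnsetEstimate(
        onset_s=onset,
        baseline_level=baseline,
        upslope_slope=float(slope),
        upslope_intercept=float(intercept),
        n_fit_samples=int(n_interior + 2),
        valid=bool(valid),
        reason=None if valid else "onset_outside_cycle",
    )


def detect_onset_pressure(cycle: SampledWaveform) -> OnsetEstimate:
    """Detect the foot of a pressure cycle as the pre-upslope minimum.

    The onset is the time (relative to the R-wave) of the minimal pressure
    on the interval from cycle start to the systolic peak; ties are broken
    to the earliest sample.  A monotone-increasing cycle yields the first
    sample, flagged valid with reason ``"onset_at_cycle_start"``.

    Raises
    ------
    NoUpslopeError
        Monotone-decreasing cycle (peak at the first sample, no upslope) or
        flat curve.
    """
    v = cycle.values
    if v.size < 2 or float(np.ptp(v)) <= _ATOL:
        raise NoUpslopeError("flat pressure curve")
    pk = int(np.argmax(v))
    if pk == 0:
        raise NoUpslopeError("monotone-decreasing pressure cycle; no upslope")
    mn = int(np.argmin(v[: pk + 1]))  # earliest index on ties
    times = cycle.times
    t_mn, t_pk = float(times[mn]), float(times[pk])
    slope = float((v[pk] - v[mn]) / (t_pk - t_mn))
    return OnsetEstimate(
        onset_s=t_mn,
        baseline_level=float(v[mn]),
        upslope_slope=slope,
        upslope_intercept=float(v[mn] - slope * t_mn),
        n_fit_samples=int(pk - mn + 1),
        valid=True,
        reason="onset_at_cycle_start" if mn == 0 else None,
    )


def aggregate_onsets(
    per_cycle: Iterable[OnsetEstimate], *, method: str = "median"
) -> OnsetEstimate:
    """Combine per-cycle onsets into a single estimate (median by default).

    Invalid per-cycle estimates are excluded; ``n_fit_samples`` of the result
    records the number of valid cycles used.

    Raises
    ------
    AggregationError
        If no valid per-cycle estimate remains.
    """
    valid = [e for e in per_cycle if e.valid]
    if not valid:
        raise AggregationError("no valid per-cycle onset to aggregate")
    agg = np.median if method == "median" else np.mean
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    return OnsetEstimate(
        onset_s=float(agg([e.onset_s for e in valid])),
        baseline_level=float(agg([e.baseline_level for e in valid])),
        upslope_slope=float(agg([e.upslope_slope for e in valid])),
        upslope_intercept=float(agg([e.upslope_intercept for e in valid])),
        n_fit_samples=len(valid),
        valid=True,
        reason=None,
    )
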
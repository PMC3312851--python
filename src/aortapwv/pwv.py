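"""Pulse wave velocity from site onsets: two-site, multi-site and pullback.

PWV = dx/dt: path length between measurement sites divided by the foot-to-
foot transit time.  With dense spatial sampling (200 centerline chords, or a
stepwise catheter pullback) the transit-time relation generalises to a
straight-line fit in the distance-time plane, onset_s = a + b * position,
with PWV = 1/b; the two-site estimator is the 2-point special case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    FootDetectionError,
    GeometryError,
    InsufficientSitesError,
    NonPhysicalPropagationError,
    SiteMatchError,
)
from .feet import aggregate_onsets, detect_onset_pressure
from .waveforms import MultiCycleRecording, OnsetEstimate, segment_cycles

__all__ = ["SiteOnset", "PWVEstimate", "two_site_pwv", "multi_site_pwv", "pullback_pwv"]

#: Pullback catheter step (m): consecutive recording positions are 5.8 cm apart.
PULLBACK_STEP_M = 0.058

_POS_TOL = 1e-9


@dataclass(frozen=True)
class SiteOnset:
    """Foot estimate at one measurement site.

    ``arc_position_m`` is the cumulative centerline distance of the site from
    the aortic-valve end of the trajectory.
    """

    arc_position_m: float
    onset: OnsetEstimate

    def __post_init__(self) -> None:
        if self.arc_position_m < 0:
            raise GeometryError("arc_position_m must be >= 0")


@dataclass(frozen=True)
class PWVEstimate:
    """A wave speed with its trajectory and regression diagnostics."""

    pwv_m_per_s: float
    method: Literal["two_site", "multi_site", "pullback"]
    delta_x_m: float
    delta_t_s: float
    n_sites: int
    slope_se_s_per_m: float = float("nan")
    fit_r2: float = float("nan")
    n_excluded: int = 0


def two_site_pwv(onset_a: SiteOnset, onset_b: SiteOnset) -> PWVEstimate:
    """Foot-to-foot PWV between two sites: dx / dt.

    dt is the downstream onset minus the upstream onset (downstream = larger
    arc position); a non-positive dt means the wave would propagate backwards
    and raises :class:`NonPhysicalPropagationError`.
    """
    if not (onset_a.onset.valid and onset_b.onset.valid):
        raise NonPhysicalPropagationError("both onsets must be valid")
    dx = onset_b.arc_position_m - onset_a.arc_position_m
    if abs(dx) <= _POS_TOL:
        raise GeometryError("identical site positions")
    up, down = (onset_a, onset_b) if dx > 0 else (onset_b, onset_a)
    dt = down.onset.onset_s - up.onset.onset_s
    if dt <= 0:
        raise NonPhysicalPropagationError(
            f"downstream onset not later than upstream (dt={dt:.6g} s)"
        )
    dx = abs(dx)
    return PWVEstimate(
        pwv_m_per_s=dx / dt,
        method="two_site",
        delta_x_m=dx,
        delta_t_s=dt,
        n_sites=2,
    )


def multi_site_pwv(
    sites: Iterable[SiteOnset],
    window: tuple[float, float] | None = None,
    *,
    method_tag: Literal["multi_site", "pullback"] = "multi_site",
) -> PWVEstimate:
    """PWV from the distance-time regression over many sites.

    Ordinary least squares of onset time on arc position over the valid
    sites whose position lies inside ``window`` (inclusive); PWV = 1/slope.
    Sites whose onset detection failed (``valid`` False) are excluded and
    counted in ``n_excluded``.

    Raises
    ------
    InsufficientSitesError
        Fewer than 2 valid in-window sites.
    NonPhysicalPropagationError
        Non-positive fitted slope.
    """
    all_sites = list(sites)
    if window is not None:
        lo, hi = window
        in_win = [s for s in all_sites if lo - _POS_TOL <= s.arc_position_m <= hi + _POS_TOL]
    else:
        in_win = all_sites
    used = [s for s in in_win if s.onset.valid]
    n_excluded = len(in_win) - len(used)
    if len(used) < 2:
        raise InsufficientSitesError(
            f"need >=2 valid sites in window, got {len(used)}"
        )
    x = np.array([s.arc_position_m for s in used])
    y = np.array([s.onset.onset_s for s in used])
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx <= _POS_TOL**2:
        raise GeometryError("site positions are not distinct")
    beta = float(np.sum((x - xm) * (y - ym)) / sxx)
    if beta <= 0:
        raise NonPhysicalPropagationError(
            f"distance-time slope not positive (beta={beta:.6g} s/m)"
        )
    alpha = ym - beta * xm
    resid = y - (alpha + beta * x)
    ssr = float(np.sum(resid**2))
    syy = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if syy <= 0 else 1.0 - ssr / syy
    se = math.sqrt(ssr / (n - 2) / sxx) if n > 2 else float("nan")
    dx = float(x.max() - x.min())
    return PWVEstimate(
        pwv_m_per_s=1.0 / beta,
        method=method_tag,
        delta_x_m=dx,
        delta_t_s=beta * dx,
        n_sites=n,
        slope_se_s_per_m=se,
        fit_r2=r2,
        n_excluded=n_excluded,
    )


def _recording_onset(rec: MultiCycleRecording, aggregate: str) -> SiteOnset:
    cycles = segment_cycles(rec)
    estimates = []
    for c in cycles:
        try:
            estimates.append(detect_onset_pressure(c))
        except FootDetectionError:
            continue
    return SiteOnset(
        arc_position_m=rec.site_position_m,
        onset=aggregate_onsets(estimates, method=aggregate),
    )


def pullback_pwv(
    recordings: Sequence[MultiCycleRecording],
    mode: str,
    *,
    site1_m: float | None = None,
    site2_m: float | None = None,
    center_m: float | None = None,
    aggregate: str = "median",
) -> PWVEstimate:
    """PWV from a stepwise catheter pullback (positions on a 5.8 cm grid).

    ``mode="regional"`` takes the two recordings nearest ``site1_m`` and
    ``site2_m`` (each within half a pullback step, else
    :class:`SiteMatchError`) and applies the two-site estimator;
    ``mode="local"`` regresses the onsets of all recordings within one
    pullback step of ``center_m`` (an 11.6 cm trajectory spanning one step
    above to one step below the site).
    """
    if not recordings:
        raise InsufficientSitesError("no pullback recordings")
    onsets = [_recording_onset(r, aggregate) for r in recordings]
    positions = np.array([o.arc_position_m for o in onsets])

    if mode == "regional":
        if site1_m is None or site2_m is None:
            raise ValueError("regional mode needs site1_m and site2_m")
        picked = []
        for target in (site1_m, site2_m):
            i = int(np.argmin(np.abs(positions - target)))
            if abs(positions[i] - target) > PULLBACK_STEP_M / 2 + _POS_TOL:
                raise SiteMatchError(
                    f"no recording within {PULLBACK_STEP_M / 2:.3f} m of {target} m"
                )
            picked.append(onsets[i])
        est = two_site_pwv(picked[0], picked[1])
        return PWVEstimate(
            pwv_m_per_s=est.pwv_m_per_s,
            method="pullback",
            delta_x_m=est.delta_x_m,
            delta_t_s=est.delta_t_s,
            n_sites=2,
        )
    if mode == "local":
        if center_m is None:
            raise ValueError("local mode needs center_m")
        window = (center_m - PULLBACK_STEP_M, center_m + PULLBACK_STEP_M)
        return multi_site_pwv(onsets, window, method_tag="pullback")
    raise ValueError(f"unknown pullback mode: {mode!r}")
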
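"""Sampled physiologic waveforms and R-wave segmentation.

A :class:`SampledWaveform` is a uniformly sampled signal (velocity in m/s,
pressure in mmHg or lumen area in mm^2) over one or more cardiac cycles, with
time measured relative to the ECG R-wave trigger.  A
:class:`MultiCycleRecording` wraps a waveform spanning several cycles together
with its trigger times (for the catheter pullback these are 2 kHz recordings
of at least 10 cycles per position).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import SegmentationError

WaveformKind = Literal["velocity", "pressure", "area"]

__all__ = [
    "SampledWaveform",
    "MultiCycleRecording",
    "OnsetEstimate",
    "segment_cycles",
]


@dataclass(frozen=True)
class SampledWaveform:
    """Uniformly sampled signal over >=1 cardiac cycles.

    Parameters
    ----------
    start_time_s : float
        Time of the first sample, in seconds relative to the R-wave.
    sample_interval_s : float
        Sampling interval in seconds (> 0).
    values : numpy.ndarray
        Ordered samples; units depend on ``kind``.
    kind : {"velocity", "pressure", "area"}
        Physical quantity carried by ``values`` (m/s, mmHg, mm^2).
    rr_s : float
        Cardiac cycle duration in seconds (> 0).  For single-cycle cyclic
        waveforms the samples span exactly one RR interval.
    """

    start_time_s: float
    sample_interval_s: float
    values: np.ndarray
    kind: WaveformKind
    rr_s: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if self.rr_s <= 0:
            raise ValueError("rr_s must be > 0")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the R-wave."""
        return self.start_time_s + np.arange(self.n) * self.sample_interval_s

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + (self.n - 1) * self.sample_interval_s

    def shifted(self, delta_s: float) -> "SampledWaveform":
        """Return a copy shifted in time by ``delta_s``."""
        return replace(self, start_time_s=self.start_time_s + delta_s)


@dataclass(frozen=True)
class MultiCycleRecording:
    """A waveform spanning several cycles plus its R-wave trigger times.

    ``site_position_m`` is the arc-length position of the measurement site
    along the aortic centerline, measured from the aortic-valve end.
    """

    waveform: SampledWaveform
    r_wave_times_s: np.ndarray
    site_position_m: float

    def __post_init__(self) -> None:
        tr = np.asarray(self.r_wave_times_s, dtype=float)
        object.__setattr__(self, "r_wave_times_s", tr)
        if tr.ndim != 1:
            raise ValueError("r_wave_times_s must be 1-D")
        if tr.size >= 2 and not np.all(np.diff(tr) > 0):
            raise ValueError("r_wave_times_s must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return max(0, int(self.r_wave_times_s.size) - 1)


@dataclass(frozen=True)
class OnsetEstimate:
    """Systolic wave-front foot time with its fit diagnostics.

    ``onset_s`` is the foot time in seconds relative to the R-wave; for
    velocity curves it is the intersection of the diastolic baseline with the
    20-80% upslope regression line, for pressure curves the time of the
    pre-upslope minimum.  Sub-sample onsets are real-valued (not snapped to
    the sampling grid).
    """

    onset_s: float
    baseline_level: float
    upslope_slope: float
    upslope_intercept: float
    n_fit_samples: int
    valid: bool = True
    reason: str | None = None


def segment_cycles(recording: MultiCycleRecording) -> list[SampledWaveform]:
    """Split a multi-cycle recording into one waveform per R-R interval.

    Each returned cycle starts at its R-wave (``times`` are relative to the
    trigger) and holds the samples with original time in
    ``[trigger_i, trigger_{i+1})``; concatenating the cycles reproduces the
    recorded samples between the first and last trigger in order.

    Raises
    ------
    SegmentationError
        If fewer than 2 triggers are given, a trigger falls outside the
        recording span, or an R-R interval contains no sample.
    """
    wf = recording.waveform
    triggers = recording.r_wave_times_s
    if triggers.size < 2:
        raise SegmentationError("need at least 2 R-wave triggers")
    t0, t1 = wf.start_time_s, wf.end_time_s
    eps = 1e-12 * max(1.0, abs(t1))
    if triggers[0] < t0 - eps or triggers[-1] > t1 + eps:
        raise SegmentationError("R-wave trigger outside the recording span")
    times = wf.times
    cycles: list[SampledWaveform] = []
    # half-open [trig_i, trig_{i+1}) slices on the sample grid
    idx = np.searchsorted(times, triggers - eps, side="left")
    for i in range(triggers.size - 1):
        a, b = int(idx[i]), int(idx[i + 1])
        if b <= a:
            raise SegmentationError(f"no samples in R-R interval {i}")
        cycles.append(
            SampledWaveform(
                start_time_s=float(times[a] - triggers[i]),
                sample_interval_s=wf.sample_interval_s,
                values=wf.values[a:b].copy(),
                kind=wf.kind,
                rr_s=float(triggers[i + 1] - triggers[i]),
            )
        )
    return cycles
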
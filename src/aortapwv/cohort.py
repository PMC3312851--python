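"""Synthetic cohort generator with Bramwell-Hill-consistent ground truth.

Each simulated subject is a self-consistent hemodynamic world: a systolic
wave front with a known local wave speed propagates along a straight-line
aortic trajectory; pressure, velocity and luminal-area signals at any arc
position are delayed copies of a common cycle template.  The generated
streams mirror the study's acquisitions:

* a stepwise catheter pullback: 2 kHz multi-cycle pressure recordings at
  positions 5.8 cm apart, with per-cycle (respiration-like) onset jitter;
* in-plane CMR: 35-phase maximal-velocity curves at 200 centerline chords;
* through-plane CMR: 35-phase velocity curves at the two transection sites;
* a per-phase lumen-area series at the local site, linearly coupled to the
  local pressure through the subject's distensibility (so the distensibility
  measurement pipeline recovers the truth exactly in the noiseless limit);
* a brachial-cuff pulse pressure, biased and noisy relative to the central
  aortic pulse pressure.

Subject truths satisfy D = 1/(rho * PWV_local^2) exactly; the regional
(arch) wave speed may differ from the local one by a configurable ratio.
A ``model_violation_sd`` knob perturbs the area response multiplicatively to
create realistic scatter between modeled and measured wave speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bramwell import MMHG_TO_PA, BloodConstants
from .errors import ConfigError
from .waveforms import MultiCycleRecording, SampledWaveform

__all__ = [
    "TemplateShape",
    "SubjectTruth",
    "CohortConfig",
    "Cohort",
    "SubjectData",
    "waveform_template",
    "draw_truths",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class TemplateShape:
    """Shape of the unit-amplitude cardiac cycle template.

    Phases are fractions of the RR interval.  The upstroke is linear from
    the foot to the peak (so the 20-80% band regression extrapolates to the
    foot exactly); the systolic decay is a raised cosine with an optional
    Gaussian dicrotic bump; ``tail_level`` sets a small declining pre-foot
    tail (used for pressure, where the pre-upslope minimum must be unique at
    the foot) and is 0 for velocity (constant diastolic flow).

    Defaults place the foot at phase 3/35 and the peak at 7/35 so both land
    exactly on a 35-phase sampling grid.
    """

    foot_phase: float = 3.0 / 35.0
    upstroke_frac: float = 4.0 / 35.0
    decay_frac: float = 0.30
    dicrotic_amp: float = 0.10
    dicrotic_delay_frac: float = 0.18
    dicrotic_width_frac: float = 0.04
    tail_level: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.foot_phase < 1) or not (0 < self.upstroke_frac < 1):
            raise ConfigError("foot phase and upstroke must lie in (0, 1)")
        if self.foot_phase + self.upstroke_frac + self.decay_frac >= 1:
            raise ConfigError("cycle template does not fit in one RR interval")
        if not (0 <= self.tail_level < 0.2):
            raise ConfigError("tail_level must be small and non-negative")


def waveform_template(phase, shape: TemplateShape = TemplateShape()):
    """Unit-amplitude cycle template evaluated at phase (fraction of RR).

    Zero (or a small declining tail) during late diastole, linear upstroke
    from the foot to peak 1, raised-cosine decay with an optional dicrotic
    bump, then the flat tail.  The analytic foot is at ``shape.foot_phase``;
    the 20-80% band of the upstroke is strictly monotone.
    """
    p = np.mod(np.asarray(phase, dtype=float), 1.0)
    f, u, d = shape.foot_phase, shape.upstroke_frac, shape.decay_frac
    peak = f + u
    tail = shape.tail_level
    out = np.empty_like(p)

    pre = p < f
    out[pre] = tail * (1.0 - p[pre] / f)
    ups = (p >= f) & (p < peak)
    out[ups] = (p[ups] - f) / u
    dec = (p >= peak) & (p < peak + d)
    out[dec] = tail + (1.0 - tail) * 0.5 * (1.0 + np.cos(np.pi * (p[dec] - peak) / d))
    late = p >= peak + d
    out[late] = tail
    if shape.dicrotic_amp > 0:
        # compact-support raised-cosine bump: exactly zero outside
        # [center - hw, center + hw], so peak and foot values stay exact
        center = peak + shape.dicrotic_delay_frac
        hw = 2.5 * shape.dicrotic_width_frac
        u = (p - center) / hw
        inside = np.abs(u) < 1.0
        out = np.where(
            inside, out + shape.dicrotic_amp * np.cos(0.5 * np.pi * u) ** 2, out
        )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth of one simulated subject.

    Invariant: ``D_per_Pa = 1 / (rho * pwv_local^2)`` exactly, so every
    model-based estimator has a well-defined target.
    """

    pwv_local_m_per_s: float
    pwv_regional_m_per_s: float
    D_per_Pa: float
    pp_aortic_mmHg: float
    pp_cuff_mmHg: float
    A_min_mm2: float
    dbp_mmHg: float
    rr_s: float
    velocity_amp_m_per_s: float = 1.0

    def validate(self, rho: float) -> None:
        vals = [
            self.pwv_local_m_per_s,
            self.pwv_regional_m_per_s,
            self.D_per_Pa,
            self.pp_aortic_mmHg,
            self.pp_cuff_mmHg,
            self.A_min_mm2,
            self.dbp_mmHg,
            self.rr_s,
            self.velocity_amp_m_per_s,
        ]
        if any(v <= 0 for v in vals):
            raise ConfigError("all subject truth fields must be positive")
        d_bh = 1.0 / (rho * self.pwv_local_m_per_s**2)
        if abs(self.D_per_Pa / d_bh - 1.0) > 1e-9:
            raise ConfigError("truth violates D = 1/(rho * pwv_local^2)")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the emulated study: 17 subjects, local wave speed
    7.0 +- 1.6 m/s, central pulse pressure 53 +- 15 mmHg, 2 kHz pressure
    recordings of 10 cycles at pullback positions 5.8 cm apart, 35 CMR
    phases per cycle and 200 chords over a 29 cm trajectory with the
    through-plane transection sites 11.6 cm apart.  The brachial cuff reads
    the central pulse pressure with a -8 mmHg bias (automated cuff devices
    under-read the central pulse pressure) and 4 mmHg device noise.
    """

    n_subjects: int = 17
    seed: int = 0
    pwv_mean: float = 7.0
    pwv_sd: float = 1.6
    pwv_min: float = 3.0
    pp_mean: float = 53.0
    pp_sd: float = 15.0
    pp_min: float = 20.0
    a_min_mean: float = 450.0
    a_min_sd: float = 80.0
    a_min_floor: float = 200.0
    dbp_mean: float = 76.0
    dbp_sd: float = 13.0
    dbp_min: float = 40.0
    rr_mean_s: float = 1.0
    rr_sd_s: float = 0.1
    rr_min_s: float = 0.6
    cuff_bias_mmHg: float = -8.0
    cuff_noise_sd: float = 4.0
    onset_jitter_sd_s: float = 0.003
    velocity_noise_sd: float = 0.015
    velocity_amp_rel_spread: float = 0.2
    cmr_phases_per_cycle: int = 35
    pressure_rate_hz: float = 2000.0
    n_cycles_pressure: int = 10
    pullback_step_m: float = 0.058
    n_pullback_positions: int = 6
    trajectory_length_m: float = 0.29
    n_chords: int = 200
    site1_m: float = 0.058
    site2_m: float = 0.174
    regional_local_pwv_ratio: float = 0.95
    model_violation_sd: float = 0.0
    rho: float = 1059.0
    shape: TemplateShape = field(default_factory=TemplateShape)
    pressure_tail_level: float = 0.02

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.shape.upstroke_frac * self.cmr_phases_per_cycle <= 2:
            raise ConfigError("upstroke must exceed 2 CMR phase intervals")
        if not (0.5 < self.regional_local_pwv_ratio <= 2.0):
            raise ConfigError("regional_local_pwv_ratio out of supported range")
        if self.site2_m <= self.site1_m:
            raise ConfigError("site2 must be downstream of site1")
        span = (self.n_pullback_positions - 1) * self.pullback_step_m
        if self.site2_m + self.pullback_step_m > span + 1e-9:
            raise ConfigError("pullback grid does not cover the local trajectory")

    @property
    def pullback_positions_m(self) -> np.ndarray:
        return np.arange(self.n_pullback_positions) * self.pullback_step_m

    @property
    def pressure_shape(self) -> TemplateShape:
        return replace(self.shape, tail_level=self.pressure_tail_level)

    def noiseless(self) -> "CohortConfig":
        """Copy with every stochastic knob (noise, jitter, cuff bias) off."""
        return replace(
            self,
            cuff_bias_mmHg=0.0,
            cuff_noise_sd=0.0,
            onset_jitter_sd_s=0.0,
            velocity_noise_sd=0.0,
            model_violation_sd=0.0,
        )


@dataclass(frozen=True)
class SubjectData:
    """All simulated (or loaded) data streams of one subject."""

    subject_id: str
    rr_s: float
    pullback: tuple[MultiCycleRecording, ...]
    chord_positions_m: np.ndarray
    chord_curves: tuple[SampledWaveform, ...]
    tp_positions_m: tuple[float, float]
    tp_curves: tuple[SampledWaveform, SampledWaveform]
    area_curve: SampledWaveform
    cuff_pp_mmHg: float
    truth: SubjectTruth | None = None


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    subjects: tuple[SubjectData, ...]

    def truth_table(self):
        import pandas as pd

        rows = []
        for s in self.subjects:
            t = s.truth
            rows.append(
                {
                    "subject": s.subject_id,
                    "pwv_local_m_per_s": t.pwv_local_m_per_s,
                    "pwv_regional_m_per_s": t.pwv_regional_m_per_s,
                    "D_per_Pa": t.D_per_Pa,
                    "pp_aortic_mmHg": t.pp_aortic_mmHg,
                    "pp_cuff_mmHg": t.pp_cuff_mmHg,
                    "A_min_mm2": t.A_min_mm2,
                    "dbp_mmHg": t.dbp_mmHg,
                    "rr_s": t.rr_s,
                    "velocity_amp_m_per_s": t.velocity_amp_m_per_s,
                }
            )
        return pd.DataFrame(rows)


def _trunc_normal(rng, mean, sd, floor, size):
    """Normal draws with resampling below ``floor``."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out < floor
        if not np.any(bad):
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ConfigError("truncation floor too far in the distribution tail")


def draw_truths(
    n: int, config: CohortConfig, rng: np.random.Generator
) -> list[SubjectTruth]:
    """Draw per-subject ground truths from the configured population."""
    pwv = _trunc_normal(rng, config.pwv_mean, config.pwv_sd, config.pwv_min, n)
    pp = _trunc_normal(rng, config.pp_mean, config.pp_sd, config.pp_min, n)
    a_min = _trunc_normal(rng, config.a_min_mean, config.a_min_sd, config.a_min_floor, n)
    dbp = _trunc_normal(rng, config.dbp_mean, config.dbp_sd, config.dbp_min, n)
    rr = _trunc_normal(rng, config.rr_mean_s, config.rr_sd_s, config.rr_min_s, n)
    amp = rng.uniform(
        1.0 - config.velocity_amp_rel_spread, 1.0 + config.velocity_amp_rel_spread, n
    )
    cuff_noise = (
        rng.normal(0.0, config.cuff_noise_sd, n)
        if config.cuff_noise_sd > 0
        else np.zeros(n)
    )
    truths = []
    for i in range(n):
        pp_cuff = max(5.0, pp[i] + config.cuff_bias_mmHg + cuff_noise[i])
        truths.append(
            SubjectTruth(
                pwv_local_m_per_s=float(pwv[i]),
                pwv_regional_m_per_s=float(config.regional_local_pwv_ratio * pwv[i]),
                D_per_Pa=float(1.0 / (config.rho * pwv[i] ** 2)),
                pp_aortic_mmHg=float(pp[i]),
                pp_cuff_mmHg=float(pp_cuff),
                A_min_mm2=float(a_min[i]),
                dbp_mmHg=float(dbp[i]),
                rr_s=float(rr[i]),
                velocity_amp_m_per_s=float(amp[i]),
            )
        )
    return truths


def _transit_fn(truth: SubjectTruth, config: CohortConfig):
    """Arc-position -> transit-time map.

    Piecewise-linear wave arrival: the segment within one pullback step of
    site 2 propagates at the local speed; the upstream (arch) segment speed
    is set so that the two-site transit between sites 1 and 2 equals the
    regional truth exactly.
    """
    v_loc = truth.pwv_local_m_per_s
    v_reg = truth.pwv_regional_m_per_s
    s1, s2, step = config.site1_m, config.site2_m, config.pullback_step_m
    sb = s2 - step
    dt_total = (s2 - s1) / v_reg
    dt_local = (s2 - sb) / v_loc
    dt_arch = dt_total - dt_local
    if dt_arch <= 0:
        raise ConfigError("regional/local speed ratio incompatible with geometry")
    v_arch = (sb - s1) / dt_arch

    def transit(s):
        s = np.asarray(s, dtype=float)
        return np.minimum(s, sb) / v_arch + np.maximum(s - sb, 0.0) / v_loc

    return transit


def simulate_subject(
    truth: SubjectTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str = "S01",
) -> SubjectData:
    """Generate all data streams of one subject from its ground truth."""
    config.validate()
    truth.validate(config.rho)
    rr = truth.rr_s
    transit = _transit_fn(truth, config)
    shape_v = config.shape
    shape_p = config.pressure_shape

    # --- catheter pullback: 2 kHz multi-cycle pressure recordings ---
    dt_p = 1.0 / config.pressure_rate_hz
    n_cyc = config.n_cycles_pressure
    triggers = np.arange(n_cyc + 1) * rr
    t = np.arange(0.0, (n_cyc + 0.25) * rr, dt_p)
    recordings = []
    for s in config.pullback_positions_m:
        delay = float(transit(s))
        jitter = (
            rng.normal(0.0, config.onset_jitter_sd_s, n_cyc + 1)
            if config.onset_jitter_sd_s > 0
            else np.zeros(n_cyc + 1)
        )
        cyc_idx = np.clip(np.floor(t / rr).astype(int), 0, n_cyc)
        phase = (t - cyc_idx * rr - delay - jitter[cyc_idx]) / rr
        p_vals = truth.dbp_mmHg + truth.pp_aortic_mmHg * waveform_template(
            phase, shape_p
        )
        recordings.append(
            MultiCycleRecording(
                waveform=SampledWaveform(0.0, dt_p, p_vals, "pressure", rr),
                r_wave_times_s=triggers,
                site_position_m=float(s),
            )
        )

    # --- in-plane CMR: 35-phase maximal-velocity curves at 200 chords ---
    n_ph = config.cmr_phases_per_cycle
    dt_c = rr / n_ph
    t_ph = np.arange(n_ph) * dt_c
    s_chords = np.linspace(0.0, config.trajectory_length_m, config.n_chords)
    phases = (t_ph[None, :] - transit(s_chords)[:, None]) / rr
    v = truth.velocity_amp_m_per_s * waveform_template(phases, shape_v)
    if config.velocity_noise_sd > 0:
        v = v + rng.normal(0.0, config.velocity_noise_sd, v.shape)
    chord_curves = tuple(
        SampledWaveform(0.0, dt_c, v[i], "velocity", rr)
        for i in range(config.n_chords)
    )

    # --- through-plane CMR: velocity curves at the two transection sites ---
    tp_pos = (config.site1_m, config.site2_m)
    tp_phase = (t_ph[None, :] - transit(np.array(tp_pos))[:, None]) / rr
    v_tp = truth.velocity_amp_m_per_s * waveform_template(tp_phase, shape_v)
    if config.velocity_noise_sd > 0:
        v_tp = v_tp + rng.normal(0.0, config.velocity_noise_sd, v_tp.shape)
    tp_curves = (
        SampledWaveform(0.0, dt_c, v_tp[0], "velocity", rr),
        SampledWaveform(0.0, dt_c, v_tp[1], "velocity", rr),
    )

    # --- lumen-area series at site 2, linearly coupled to local pressure ---
    d_eff = truth.D_per_Pa
    if config.model_violation_sd > 0:
        d_eff *= float(np.exp(rng.normal(0.0, config.model_violation_sd)))
    # retrospectively gated area series, phase-aligned to its own cycle foot
    # (the absolute trigger offset is irrelevant for the distension)
    phase_loc = t_ph / rr
    p_loc = truth.pp_aortic_mmHg * waveform_template(phase_loc, shape_p)
    area = truth.A_min_mm2 * (1.0 + d_eff * p_loc * MMHG_TO_PA)
    area_curve = SampledWaveform(0.0, dt_c, area, "area", rr)

    return SubjectData(
        subject_id=subject_id,
        rr_s=rr,
        pullback=tuple(recordings),
        chord_positions_m=s_chords,
        chord_curves=chord_curves,
        tp_positions_m=tp_pos,
        tp_curves=tp_curves,
        area_curve=area_curve,
        cuff_pp_mmHg=truth.pp_cuff_mmHg,
        truth=truth,
    )


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate ``config.n_subjects`` independent subjects, seeded.

    Identical config (including seed) yields identical datasets.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    rng_truth = np.random.default_rng(children[0])
    truths = draw_truths(config.n_subjects, config, rng_truth)
    subjects = []
    for i, truth in enumerate(truths):
        rng = np.random.default_rng(children[i + 1])
        subjects.append(
            simulate_subject(truth, config, rng, subject_id=f"S{i + 1:02d}")
        )
    return Cohort(config=config, subjects=tuple(subjects))
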
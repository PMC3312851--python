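import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aortapwv as ap

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> ap.CohortConfig:
    return dataclasses.replace(ap.CohortConfig(), seed=1)


@pytest.fixture(scope="session")
def noiseless_config(default_config) -> ap.CohortConfig:
    return default_config.noiseless()


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config) -> ap.Cohort:
    return ap.simulate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def clean_truth(noiseless_config) -> ap.SubjectTruth:
    """One deterministic, Bramwell-Hill-consistent subject truth."""
    rng = np.random.default_rng(7)
    return ap.draw_truths(1, noiseless_config, rng)[0]


def make_velocity_cycle(
    *,
    rr=1.0,
    dt=1 / 2000,
    plateau=0.05,
    onset=0.10,
    slope=8.0,
    peak=0.9,
    decay_tau=0.08,
    noise_sd=0.0,
    rng=None,
):
    """Piecewise-linear systolic cycle with an analytically known foot."""
    t = np.arange(0.0, rr, dt)
    v = np.full_like(t, plateau)
    t_peak = onset + (peak - plateau) / slope
    rise = (t >= onset) & (t < t_peak)
    v[rise] = plateau + slope * (t[rise] - onset)
    dec = t >= t_peak
    v[dec] = plateau + (peak - plateau) * np.exp(-(t[dec] - t_peak) / decay_tau)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, v.shape)
    return ap.SampledWaveform(0.0, dt, v, "velocity", rr)
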
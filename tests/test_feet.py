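import numpy as np
import pytest

import aortapwv as ap
from aortapwv.errors import AggregationError, NoUpslopeError

from conftest import make_velocity_cycle


class TestVelocityOnset:
    def test_analytic_piecewise_cycle_recovers_exact_foot(self):
        cycle = make_velocity_cycle(onset=0.10)
        est = ap.detect_onset_velocity(cycle)
        # the plateau level and the linear rise intersect exactly at the foot
        assert est.onset_s == pytest.approx(0.100, abs=1e-6)
        assert est.baseline_level == pytest.approx(0.05, abs=1e-9)
        assert est.upslope_slope == pytest.approx(8.0, rel=1e-9)
        assert est.valid

    def test_flat_curve_has_no_upslope(self):
        wf = ap.SampledWaveform(0.0, 1 / 2000, np.full(2000, 0.05), "velocity", 1.0)
        with pytest.raises(NoUpslopeError):
            ap.detect_onset_velocity(wf)

    def test_noisy_replicates_are_unbiased(self):
        rng = np.random.default_rng(42)
        onsets = []
        for _ in range(200):
            cycle = make_velocity_cycle(onset=0.10, noise_sd=0.02, rng=rng)
            onsets.append(ap.detect_onset_velocity(cycle).onset_s)
        assert abs(np.mean(onsets) - 0.100) < 0.005

    @pytest.mark.parametrize("delta", [-0.05, 0.013, 0.2])
    def test_time_shift_equivariance(self, delta):
        cycle = make_velocity_cycle()
        base = ap.detect_onset_velocity(cycle).onset_s
        shifted = ap.detect_onset_velocity(cycle.shifted(delta)).onset_s
        assert shifted - base == pytest.approx(delta, abs=1e-12)

    @pytest.mark.parametrize("k", [0.2, 3.0, 117.0])
    def test_amplitude_scale_invariance(self, k):
        cycle = make_velocity_cycle()
        scaled = ap.SampledWaveform(
            cycle.start_time_s,
            cycle.sample_interval_s,
            k * cycle.values,
            "velocity",
            cycle.rr_s,
        )
        a = ap.detect_onset_velocity(cycle)
        b = ap.detect_onset_velocity(scaled)
        assert b.onset_s == pytest.approx(a.onset_s, abs=1e-12)

    def test_closed_form_matches_grid_intersection_oracle(self):
        """Line intersection equals a dense 1-us brute-force search."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            cycle = make_velocity_cycle(
                plateau=rng.uniform(0.0, 0.1),
                onset=rng.uniform(0.05, 0.3),
                slope=rng.uniform(3, 15),
                peak=rng.uniform(0.6, 1.4),
                noise_sd=0.01,
                rng=rng,
            )
            est = ap.detect_onset_velocity(cycle)
            grid = np.arange(0.0, cycle.rr_s, 1e-6)
            upslope = est.upslope_intercept + est.upslope_slope * grid
            t_star = grid[np.argmin(np.abs(upslope - est.baseline_level))]
            assert abs(t_star - est.onset_s) <= 1e-6


class TestPressureOnset:
    @staticmethod
    def _pressure_cycle(min_at=0.08, rr=1.0, dt=1 / 2000):
        t = np.arange(0.0, rr, dt)
        # declining diastolic tail into a unique minimum, then a systolic rise
        p = np.where(
            t < min_at,
            80.0 + 2.0 * (min_at - t) / min_at,
            80.0 + 50.0 * np.clip((t - min_at) / 0.1, 0, 1) * np.exp(-(t - min_at) / 0.4),
        )
        return ap.SampledWaveform(0.0, dt, p, "pressure", rr)

    def test_constructed_minimum_location_is_recovered(self):
        est = ap.detect_onset_pressure(self._pressure_cycle(min_at=0.08))
        assert est.onset_s == pytest.approx(0.080, abs=1e-3)
        assert est.valid and est.reason is None
        assert est.upslope_slope > 0

    def test_monotone_increasing_cycle_flags_cycle_start(self):
        wf = ap.SampledWaveform(0.0, 0.01, np.linspace(60, 120, 100), "pressure", 1.0)
        est = ap.detect_onset_pressure(wf)
        assert est.onset_s == 0.0
        assert est.valid and est.reason == "onset_at_cycle_start"

    def test_tied_minima_take_earliest_sample(self):
        v = np.array([5.0, 3.0, 1.0, 1.0, 2.0, 8.0, 4.0])
        wf = ap.SampledWaveform(0.0, 0.1, v, "pressure", 0.7)
        est = ap.detect_onset_pressure(wf)
        assert est.onset_s == pytest.approx(0.2)

    def test_monotone_decreasing_cycle_has_no_upslope(self):
        wf = ap.SampledWaveform(0.0, 0.01, np.linspace(120, 60, 100), "pressure", 1.0)
        with pytest.raises(NoUpslopeError):
            ap.detect_onset_pressure(wf)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_argmin_oracle_on_random_cycles(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 1.0, 1 / 500)
        p = 80 + 20 * np.sin(2 * np.pi * (t - rng.uniform(0, 1))) + rng.normal(0, 1, t.size)
        wf = ap.SampledWaveform(0.0, 1 / 500, p, "pressure", 1.0)
        est = ap.detect_onset_pressure(wf)
        pk = int(np.argmax(p))
        assert est.onset_s == pytest.approx(t[int(np.argmin(p[: pk + 1]))])


class TestAggregation:
    @staticmethod
    def _est(onset):
        return ap.OnsetEstimate(onset, 0.0, 1.0, 0.0, 5, True, None)

    def test_odd_count_median(self):
        agg = ap.aggregate_onsets([self._est(o) for o in (0.080, 0.082, 0.078)])
        assert agg.onset_s == pytest.approx(0.080)
        assert agg.n_fit_samples == 3

    def test_single_estimate_is_identity(self):
        agg = ap.aggregate_onsets([self._est(0.123)])
        assert agg.onset_s == pytest.approx(0.123)

    def test_median_shrugs_off_gross_outlier(self):
        rng = np.random.default_rng(0)
        onsets = list(0.080 + rng.normal(0, 0.001, 9))
        clean_median = float(np.median(onsets))
        agg = ap.aggregate_onsets([self._est(o) for o in onsets + [0.180]])
        assert abs(agg.onset_s - clean_median) < 0.002

    def test_no_valid_cycles_is_an_error(self):
        bad = ap.OnsetEstimate(0.1, 0.0, 1.0, 0.0, 5, False, "onset_outside_cycle")
        with pytest.raises(AggregationError):
            ap.aggregate_onsets([bad])

    def test_mean_aggregation_behind_flag(self):
        agg = ap.aggregate_onsets(
            [self._est(o) for o in (0.0, 0.1, 0.5)], method="mean"
        )
        assert agg.onset_s == pytest.approx(0.2)
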
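import dataclasses

import numpy as np
import pytest

import aortapwv as ap
from aortapwv.cohort import _transit_fn
from aortapwv.errors import ConfigError


class TestTemplate:
    def test_zero_before_foot_and_unit_peak(self):
        shape = ap.TemplateShape()
        assert ap.waveform_template(shape.foot_phase * 0.5, shape) == 0.0
        assert ap.waveform_template(0.0, shape) == 0.0
        assert ap.waveform_template(shape.foot_phase + shape.upstroke_frac, shape) == (
            pytest.approx(1.0)
        )

    def test_upstroke_band_strictly_monotone(self):
        shape = ap.TemplateShape()
        p = np.linspace(shape.foot_phase, shape.foot_phase + shape.upstroke_frac, 200)
        v = ap.waveform_template(p, shape)
        band = (v >= 0.2) & (v <= 0.8)
        assert np.all(np.diff(v[band]) > 0)

    def test_detection_recovers_analytic_foot_at_2khz(self):
        shape = ap.TemplateShape()
        rr = 1.0
        t = np.arange(0.0, rr, 1 / 2000)
        wf = ap.SampledWaveform(
            0.0, 1 / 2000, ap.waveform_template(t / rr, shape), "velocity", rr
        )
        est = ap.detect_onset_velocity(wf)
        assert est.onset_s == pytest.approx(shape.foot_phase * rr, abs=1e-3)

    def test_too_coarse_upstroke_is_a_config_error(self):
        cfg = dataclasses.replace(
            ap.CohortConfig(),
            shape=dataclasses.replace(ap.TemplateShape(), upstroke_frac=0.05),
            cmr_phases_per_cycle=35,
        )
        with pytest.raises(ConfigError):
            cfg.validate()


class TestTruths:
    def test_truncation_respected_over_many_draws(self, default_config):
        rng = np.random.default_rng(123)
        truths = ap.draw_truths(10_000, default_config, rng)
        pwv = np.array([t.pwv_local_m_per_s for t in truths])
        assert pwv.min() >= default_config.pwv_min
        assert min(t.pp_aortic_mmHg for t in truths) >= default_config.pp_min
        assert min(t.A_min_mm2 for t in truths) >= default_config.a_min_floor

    def test_truths_are_bramwell_hill_consistent(self, default_config):
        rng = np.random.default_rng(5)
        for t in ap.draw_truths(50, default_config, rng):
            assert t.D_per_Pa * default_config.rho * t.pwv_local_m_per_s**2 == (
                pytest.approx(1.0, rel=1e-12)
            )

    def test_inconsistent_truth_is_rejected(self, noiseless_config, clean_truth):
        bad = dataclasses.replace(clean_truth, D_per_Pa=clean_truth.D_per_Pa * 1.01)
        with pytest.raises(ConfigError):
            ap.simulate_subject(bad, noiseless_config, np.random.default_rng(0))


class TestSimulation:
    def test_same_seed_gives_identical_datasets(self, default_config):
        a = ap.simulate_cohort(default_config)
        b = ap.simulate_cohort(default_config)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(
                sa.pullback[0].waveform.values, sb.pullback[0].waveform.values
            )
            np.testing.assert_array_equal(
                sa.chord_curves[0].values, sb.chord_curves[0].values
            )
            assert sa.cuff_pp_mmHg == sb.cuff_pp_mmHg

    def test_noiseless_local_multisite_recovery_within_3pct(
        self, noiseless_cohort, noiseless_config
    ):
        cfg = noiseless_config
        for s in noiseless_cohort.subjects:
            sites = [
                ap.SiteOnset(float(x), ap.detect_onset_velocity(c))
                for x, c in zip(s.chord_positions_m, s.chord_curves)
            ]
            est = ap.multi_site_pwv(
                sites, (cfg.site2_m - cfg.pullback_step_m - 1e-9,
                        cfg.site2_m + cfg.pullback_step_m + 1e-9)
            )
            assert est.pwv_m_per_s == pytest.approx(
                s.truth.pwv_local_m_per_s, rel=0.03
            )

    def test_noiseless_distensibility_identity(self, noiseless_cohort):
        for s in noiseless_cohort.subjects:
            a = s.area_curve.values
            d = ap.distensibility(a.max() - a.min(), a.min(), s.truth.pp_aortic_mmHg)
            assert d.D_per_Pa == pytest.approx(s.truth.D_per_Pa, rel=1e-9)

    def test_pressure_pullback_onsets_follow_the_transit_map(
        self, noiseless_cohort, noiseless_config
    ):
        s = noiseless_cohort.subjects[0]
        transit = _transit_fn(s.truth, noiseless_config)
        foot = noiseless_config.shape.foot_phase * s.rr_s
        for rec in s.pullback:
            cycles = ap.segment_cycles(rec)
            est = ap.aggregate_onsets([ap.detect_onset_pressure(c) for c in cycles])
            expected = foot + float(transit(rec.site_position_m))
            assert est.onset_s == pytest.approx(expected, abs=1e-3)

    def test_cuff_bias_lowers_modeled_pwv_cohort_mean(self, default_config):
        """Under-read cuff pulse pressure deflates the modeled wave speed."""
        for seed in range(5):
            cfg = dataclasses.replace(default_config, seed=seed)
            cohort = ap.simulate_cohort(cfg)
            cuff, cath = [], []
            for s in cohort.subjects:
                a = s.area_curve.values
                dA, amin = a.max() - a.min(), a.min()
                cuff.append(
                    ap.theoretical_pwv(ap.distensibility(dA, amin, s.cuff_pp_mmHg))
                )
                cath.append(
                    ap.theoretical_pwv(
                        ap.distensibility(dA, amin, s.truth.pp_aortic_mmHg)
                    )
                )
            assert np.mean(cuff) < np.mean(cath)
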
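"""Generator contracts: determinism, known-truth construction, dilution
mass balance, and the statistical structure of voltage/taxon tables."""

import numpy as np
import pytest
from scipy import stats

from darkox.synthetic import (
    ChamberSimConfig,
    ConfigInfeasibleError,
    ProfileSimConfig,
    simulate_ambient_series,
    simulate_chamber_series,
    simulate_microprofile,
    simulate_taxon_table,
    simulate_voltage_survey,
)


class TestChamberSeries:
    def test_identity_case_is_constant(self):
        cfg = ChamberSimConfig(
            dop_true=0.0, scoc_true=0.0, noise_sd=0.0, drift_rate=0.0,
            initial_o2_sd=0.0, seed=1,
        )
        series, truth = simulate_chamber_series(cfg)
        assert np.allclose(series.o2, truth.initial_o2)

    def test_same_seed_bit_identical(self):
        cfg = ChamberSimConfig(seed=42)
        s1, _ = simulate_chamber_series(cfg)
        s2, _ = simulate_chamber_series(cfg)
        assert np.array_equal(s1.o2, s2.o2)
        assert np.array_equal(s1.time_s, s2.time_s)

    def test_different_seed_differs(self):
        s1, t1 = simulate_chamber_series(ChamberSimConfig(seed=1))
        s2, t2 = simulate_chamber_series(ChamberSimConfig(seed=2))
        assert not np.array_equal(s1.o2, s2.o2)
        assert t1.initial_o2 != t2.initial_o2

    def test_unit_conversion_slope(self):
        """Net rate 5 mmol m-2 d-1 over 10 cm of water is 50 µmol l-1 d-1."""
        cfg = ChamberSimConfig(
            dop_true=5.0, scoc_true=0.0, chamber_area=484.0, water_depth=10.0,
            saturation_shape=0.0, noise_sd=0.0, drift_rate=0.0,
            initial_o2_sd=0.0, syringe_times=(), seed=1,
        )
        series, truth = simulate_chamber_series(cfg)
        assert truth.slope_umol_l_d == pytest.approx(50.0)
        t_d = series.time_s / 86400.0
        post_stir = series.time_s >= cfg.stir_off_interval * 3600.0
        slope = np.polyfit(t_d[post_stir], series.o2[post_stir], 1)[0]
        assert slope == pytest.approx(50.0, rel=1e-9)

    def test_max_matches_generating_integral(self):
        """Production reaching its maximum matches the saturating integral
        to better than 0.1 µmol l-1 (damped trajectory, realistic start)."""
        cfg = ChamberSimConfig(
            dop_true=14.0, scoc_true=0.7, saturation_shape=1.5,
            noise_sd=0.0, drift_rate=0.0, initial_o2_sd=0.0,
            syringe_times=(), seed=1,
        )
        series, truth = simulate_chamber_series(cfg)
        delta = series.o2.max() - truth.initial_o2
        assert abs(delta - truth.expected_delta(cfg.duration_h)) < 0.1
        assert truth.initial_o2 == pytest.approx(185.2)

    def test_dilution_steps_have_mass_balance_magnitude(self):
        cfg = ChamberSimConfig(
            noise_sd=0.0, drift_rate=0.0, initial_o2_sd=0.0,
            saturation_shape=0.0, seed=3,
        )
        series, truth = simulate_chamber_series(cfg)
        v = cfg.syringe_volume / 1000.0
        V = cfg.water_volume_l
        # first event: pre-event concentration from the undiluted trajectory
        te = sorted(cfg.syringe_times)[0]
        i_before = np.nonzero(series.time_s < te * 3600.0)[0][-1]
        c_before = truth.initial_o2 + truth.expected_delta(
            series.time_s[i_before] / 3600.0
        )
        expected = (c_before - cfg.ambient_o2) * v / V
        assert truth.dilution_steps[0] == pytest.approx(expected, abs=1e-9)
        i_after = np.nonzero(series.time_s >= te * 3600.0)[0][0]
        observed_jump = (
            truth.expected_delta(series.time_s[i_after] / 3600.0)
            - truth.expected_delta(series.time_s[i_before] / 3600.0)
            - (series.o2[i_after] - series.o2[i_before])
        )
        assert observed_jump == pytest.approx(truth.dilution_steps[0], abs=1e-9)

    def test_stir_off_segment_flat(self):
        cfg = ChamberSimConfig(
            noise_sd=0.0, drift_rate=0.0, initial_o2_sd=0.0, seed=4,
        )
        series, truth = simulate_chamber_series(cfg)
        off = series.time_s < cfg.stir_off_interval * 3600.0
        assert np.allclose(series.o2[off], truth.initial_o2)

    def test_gaps_removed_not_interpolated(self):
        cfg = ChamberSimConfig(gap_intervals=((5.0, 8.0),), seed=5)
        series, _ = simulate_chamber_series(cfg)
        in_gap = (series.time_s >= 5 * 3600.0) & (series.time_s < 8 * 3600.0)
        assert not np.any(in_gap)
        full, _ = simulate_chamber_series(ChamberSimConfig(seed=5))
        assert len(series) < len(full)

    def test_infeasible_config_rejected(self):
        cfg = ChamberSimConfig(
            dop_true=0.0, scoc_true=500.0, noise_sd=0.0, drift_rate=0.0,
            initial_o2_sd=0.0, saturation_shape=0.0, seed=1,
        )
        with pytest.raises(ConfigInfeasibleError):
            simulate_chamber_series(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ChamberSimConfig(chamber_area=-1.0)
        with pytest.raises(ValueError):
            ChamberSimConfig(syringe_volume=1e6)
        with pytest.raises(ValueError):
            ChamberSimConfig(noise_sd=-0.1)

    def test_ambient_trace_constant(self):
        cfg = ChamberSimConfig(noise_sd=0.0, seed=6)
        amb = simulate_ambient_series(cfg)
        assert np.allclose(amb.o2, cfg.ambient_o2)


class TestMicroprofile:
    def test_flat_when_no_flux(self):
        cfg = ProfileSimConfig(true_flux=0.0, noise_sd=0.0, seed=1)
        profile, _ = simulate_microprofile(cfg)
        assert np.allclose(profile.o2, cfg.overlying_o2)

    def test_near_surface_slope_closed_form(self):
        """Noise-free near-surface gradient equals F/(phi*Ds) exactly."""
        cfg = ProfileSimConfig(true_flux=0.7, noise_sd=0.0, seed=1)
        profile, truth = simulate_microprofile(cfg)
        i0 = truth.surface_index
        window = slice(i0, i0 + 10)
        slope = np.polyfit(profile.depths_mm[window], profile.o2[window], 1)[0]
        # hand value: 0.7 / (0.8 * 8.159e-6 cm2/s * 8640) µmol l-1 mm-1
        assert slope == pytest.approx(-0.7 / (0.8 * 8.159e-6 * 8640.0), rel=1e-9)
        assert slope == pytest.approx(-truth.gradient, rel=1e-12)

    def test_step_spacing(self):
        profile, _ = simulate_microprofile(ProfileSimConfig(step_mm=0.05, seed=2))
        assert np.allclose(np.diff(profile.depths_mm), 0.05)

    def test_deterministic(self):
        p1, _ = simulate_microprofile(ProfileSimConfig(seed=9))
        p2, _ = simulate_microprofile(ProfileSimConfig(seed=9))
        assert np.array_equal(p1.o2, p2.o2)

    def test_infeasible_gradient_rejected(self):
        with pytest.raises(ConfigInfeasibleError):
            simulate_microprofile(
                ProfileSimConfig(true_flux=50.0, noise_sd=0.0, seed=1)
            )


class TestVoltageSurvey:
    def test_zero_sd_all_equal(self):
        sv = simulate_voltage_survey(5, mean_v=0.3, sd_v=0.0, seed=1)
        assert np.allclose(sv.potentials, 0.3)

    def test_background_stored_and_applied(self):
        sv = simulate_voltage_survey(5, mean_v=0.3, sd_v=0.0,
                                     background_v=0.003, seed=1)
        assert sv.background == 0.003
        assert np.allclose(sv.corrected, 0.297)

    def test_replicate_count(self):
        assert simulate_voltage_survey(20, seed=1).n == 20

    def test_requires_at_least_one_site(self):
        with pytest.raises(ValueError):
            simulate_voltage_survey(0, seed=1)


class TestTaxonTable:
    def test_rows_sum_to_one(self):
        dop = np.arange(7.0)
        df = simulate_taxon_table(7, 5, 0.5, dop, seed=1)
        assert np.allclose(df.sum(axis=1), 1.0, atol=1e-9)

    def test_perfect_rho_monotone(self):
        dop = np.array([3.0, 1.0, 7.0, 2.0, 9.0, 4.0])
        df = simulate_taxon_table(6, 4, 1.0, dop, seed=2)
        rho = stats.spearmanr(df.iloc[:, 0], dop).statistic
        assert rho == pytest.approx(1.0)

    def test_target_rho_recovered_on_average(self):
        """Monte-Carlo check of the rank-blend construction at rho=0.47."""
        dop = np.array([1.7, 3.0, 4.5, 6.0, 9.0, 12.0, 18.0])
        rhos = [
            stats.spearmanr(
                simulate_taxon_table(7, 5, 0.47, dop, seed=s).iloc[:, 0], dop
            ).statistic
            for s in range(200)
        ]
        assert abs(np.mean(rhos) - 0.47) < 0.15

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_taxon_table(3, 4, 0.5, np.arange(5.0), seed=1)
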
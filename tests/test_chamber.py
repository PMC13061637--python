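"""Chamber flux estimation: alignment, dilution inversion, net change,
decline-based SCOC and nodule densities."""

import numpy as np
import pytest

from darkox.chamber import (
    ChamberExperiment,
    ChamberFluxModel,
    align_schedule,
    correct_dilution,
    net_o2_change,
    nodule_density,
    nodule_density_summary,
    scoc_from_decline,
)
from darkox.optode import OptodeSeries
from darkox.synthetic import ChamberSimConfig, simulate_chamber_series


class TestAlignSchedule:
    def test_zero_offset_only_annotates(self):
        series = OptodeSeries(np.arange(0.0, 100.0, 10.0), np.full(10, 185.0))
        out = align_schedule(series, {"seal": 0.0, "syringe": [50.0]})
        assert np.array_equal(out.time_s, series.time_s)
        assert out.events["syringe"] == [50.0]

    def test_reindexed_to_sealing_zero(self):
        series = OptodeSeries(np.arange(0.0, 200.0, 10.0), np.full(20, 185.0))
        out = align_schedule(series, {"seal": 100.0})
        assert out.time_s[0] == -100.0
        assert 0.0 in out.time_s

    def test_syringe_events_attached(self):
        series = OptodeSeries(
            np.arange(0.0, 48 * 3600.0, 600.0),
            np.full(288, 185.0),
        )
        program = {"seal": 0.0, "syringe": [t * 3600.0 for t in (28, 38, 47)]}
        out = align_schedule(series, program)
        assert out.events["syringe"] == [28 * 3600.0, 38 * 3600.0, 47 * 3600.0]

    def test_program_outside_series_rejected(self):
        series = OptodeSeries(np.arange(0.0, 100.0, 10.0), np.full(10, 185.0))
        with pytest.raises(ValueError):
            align_schedule(series, {"seal": 1e6})


class TestDilutionCorrection:
    def test_single_event_mass_balance_by_hand(self):
        """V=2 l, v=50 ml, 400 -> 394.625 µmol l-1; correction restores 400."""
        series = OptodeSeries(
            np.array([0.0, 10.0, 20.0]), np.array([400.0, 400.0, 394.625])
        )
        out = correct_dilution(series, [15.0], 2.0, 50.0, ambient_o2=185.0)
        assert out.o2[2] == pytest.approx(400.0, abs=1e-12)

    def test_ambient_equal_chamber_is_identity(self):
        series = OptodeSeries(np.array([0.0, 10.0, 20.0]), np.full(3, 250.0))
        out = correct_dilution(series, [15.0], 2.0, 50.0, ambient_o2=250.0)
        assert np.array_equal(out.o2, series.o2)

    def test_exact_inverse_of_generator(self, clean_chamber_config):
        """Noise-free diluted series corrected back to the undiluted one to
        machine precision, across all three syringe events."""
        cfg = clean_chamber_config
        undiluted_cfg = ChamberSimConfig(
            **{**vars(cfg), "syringe_times": ()}
        )
        diluted, _ = simulate_chamber_series(cfg)
        undiluted, _ = simulate_chamber_series(undiluted_cfg)
        out = correct_dilution(
            diluted,
            [t * 3600.0 for t in cfg.syringe_times],
            cfg.water_volume_l,
            cfg.syringe_volume,
            ambient_o2=cfg.ambient_o2,
        )
        assert np.max(np.abs(out.o2 - undiluted.o2)) < 1e-12

    def test_corrected_max_not_below_raw_max(self):
        series, _ = simulate_chamber_series(
            ChamberSimConfig(noise_sd=0.0, drift_rate=0.0, initial_o2_sd=0.0, seed=7)
        )
        cfg = ChamberSimConfig(seed=7)
        out = correct_dilution(
            series,
            [t * 3600.0 for t in cfg.syringe_times],
            cfg.water_volume_l,
            cfg.syringe_volume,
            ambient_o2=cfg.ambient_o2,
        )
        assert out.o2.max() >= series.o2.max()

    def test_missing_ambient_rejected(self):
        series = OptodeSeries(np.array([0.0, 10.0]), np.array([200.0, 199.0]))
        with pytest.raises(ValueError, match="ambient"):
            correct_dilution(series, [5.0], 2.0, 50.0, ambient_o2=None)


class TestNetO2Change:
    def test_flat_series_is_neutral(self):
        series = OptodeSeries(np.arange(0.0, 3600.0, 10.0), np.full(360, 185.0))
        exp = ChamberExperiment(id="x", water_depth=10.0)
        res = net_o2_change(series, exp)
        assert res.delta_c == 0.0
        assert res.classification == "neutral"

    def test_total_net_o2_arithmetic(self):
        """185.2 -> 819 µmol l-1 in 2 l of water is 1267.6 µmol of O2."""
        t = np.arange(0.0, 47 * 3600.0, 600.0)
        c = 185.2 + (819.0 - 185.2) * t / t[-1]
        exp = ChamberExperiment(id="x", chamber_area=484.0, water_depth=1000 * 2.0 / 484.0)
        res = net_o2_change(OptodeSeries(t, c), exp, initial_window_s=0.0,
                            max_window_s=0.0)
        assert res.delta_c == pytest.approx(633.8)
        assert res.total_net_o2 == pytest.approx(1267.6)

    def test_round_trip_recovers_net_rate(self, clean_chamber_config, experiment_for):
        series, truth = simulate_chamber_series(clean_chamber_config)
        exp = experiment_for(clean_chamber_config)
        res = ChamberFluxModel(series, exp, dilution_correction=True).fit()
        assert res.dop_rate == pytest.approx(truth.net_rate, rel=1e-9)

    def test_volume_unknown_flagged(self, clean_chamber_config):
        series, _ = simulate_chamber_series(clean_chamber_config)
        exp = ChamberExperiment(id="x", water_depth=None)
        res = net_o2_change(series, exp)
        assert res.total_net_o2 is None and res.dop_rate is None
        assert any("volume unknown" in f for f in res.flags)
        assert res.delta_c > 0  # concentration-only fields still present

    def test_total_scales_with_volume(self, clean_chamber_config):
        series, _ = simulate_chamber_series(clean_chamber_config)
        r1 = net_o2_change(series, ChamberExperiment(id="a", water_depth=10.0))
        r2 = net_o2_change(series, ChamberExperiment(id="b", water_depth=20.0))
        assert r2.total_net_o2 == pytest.approx(2 * r1.total_net_o2)

    def test_summary_mentions_rate(self, clean_chamber_config, experiment_for):
        series, _ = simulate_chamber_series(clean_chamber_config)
        res = ChamberFluxModel(series, experiment_for(clean_chamber_config)).fit()
        assert "DOP rate" in res.summary()
        assert res.to_record()["classification"] == "net producer"


class TestSCOCFromDecline:
    def test_slope_unit_conversion(self):
        """-10 µmol l-1 d-1 over 10 cm of water is 1.0 mmol m-2 d-1 uptake."""
        t = np.arange(0.0, 2 * 86400.0, 600.0)
        c = 200.0 - 10.0 * t / 86400.0
        exp = ChamberExperiment(id="x", water_depth=10.0)
        assert scoc_from_decline(OptodeSeries(t, c), exp) == pytest.approx(1.0)

    def test_flat_series_rejected(self):
        series = OptodeSeries(np.arange(0.0, 3600.0, 10.0), np.full(360, 185.0))
        exp = ChamberExperiment(id="x", water_depth=10.0)
        with pytest.raises(ValueError, match="not a net consumer"):
            scoc_from_decline(series, exp)

    def test_consumption_only_round_trip(self, experiment_for):
        cfg = ChamberSimConfig(
            dop_true=0.0, scoc_true=1.4, noise_sd=0.0, drift_rate=0.0,
            initial_o2_sd=0.0, saturation_shape=0.0, syringe_times=(),
            stir_off_interval=0.0, seed=2,
        )
        series, _ = simulate_chamber_series(cfg)
        assert scoc_from_decline(series, experiment_for(cfg)) == pytest.approx(
            1.4, rel=1e-9
        )


class TestNoduleDensity:
    def test_zero(self):
        assert nodule_density(0) == 0.0

    def test_chamber_count_to_areal_density(self):
        assert nodule_density(57, 484.0) == pytest.approx(57 / 0.0484)

    def test_summary_mean_se(self):
        mean, se, n = nodule_density_summary([50, 57, 63], 484.0)
        d = np.array([50, 57, 63]) / 0.0484
        assert mean == pytest.approx(d.mean())
        assert se == pytest.approx(d.std(ddof=1) / np.sqrt(3))
        assert n == 3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nodule_density(-1)
        with pytest.raises(ValueError):
            nodule_density(5, 0.0)


class TestParameterRecoveryUnderNoise:
    def test_net_rate_within_5pct_in_95_of_100_seeds(self, experiment_for):
        """Study-condition noise (0.5 µmol l-1) and drift: the max-based
        estimator stays within 5% of the generating net rate in at least
        95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            cfg = ChamberSimConfig(saturation_shape=0.0, seed=seed)
            series, truth = simulate_chamber_series(cfg)
            res = ChamberFluxModel(
                series, experiment_for(cfg), dilution_correction=True
            ).fit()
            if abs(res.dop_rate - truth.net_rate) / truth.net_rate < 0.05:
                hits += 1
        assert hits >= 95
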
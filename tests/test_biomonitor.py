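"""Tests for the load-cell pipeline: calibration, denoising, events, intake."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aviphen import biomonitor as bm
from aviphen.params import BirdParams, EnvironmentProgram, LoadCellModel
from aviphen.simulate import (
    empty_chamber_truth,
    simulate_bird_rates,
    simulate_load_cells,
)


def filtered_frame(times, values, sds=None):
    values = np.asarray(values, dtype=float)
    sds = np.zeros_like(values) if sds is None else np.asarray(sds, dtype=float)
    return pd.DataFrame({"time_s": np.asarray(times, dtype=float),
                         "value": values, "sd": sds})


class TestCalibration:
    def test_exact_line_recovered(self):
        counts = np.linspace(1000, 9000, 8)
        grams = 0.025 * counts - 3.0
        cal = bm.calibrate_load_cell(counts, grams)
        assert cal.scale_g_per_count == pytest.approx(0.025, abs=1e-12)
        assert cal.offset_g == pytest.approx(-3.0, abs=1e-9)
        assert cal.rms_g == pytest.approx(0.0, abs=1e-9)

    def test_two_point(self):
        cal = bm.calibrate_load_cell([0.0, 1000.0], [0.0, 100.0])
        assert cal.scale_g_per_count == pytest.approx(0.1)
        assert cal.offset_g == pytest.approx(0.0, abs=1e-12)

    def test_noisy_checkweights(self):
        rng = np.random.default_rng(7)
        grams = np.linspace(25, 200, 8)
        counts = (grams + 1.5) / 0.02 + rng.normal(0, 0.05 / 0.02, 8)
        cal = bm.calibrate_load_cell(counts, grams)
        assert cal.scale_g_per_count == pytest.approx(0.02, rel=5e-3)

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError):
            bm.calibrate_load_cell([1.0, 2.0], [50.0, 50.0])


class TestStablePointSelection:
    def test_constant_hour_six_points(self):
        t = np.arange(3600.0)
        out = bm.stable_point_selection(t, np.full(3600, 27.0))
        assert len(out) == 6
        np.testing.assert_allclose(out["value"], 27.0)
        np.testing.assert_allclose(out["sd"], 0.0)

    def test_quiet_half_preferred(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([27 + rng.normal(0, 0.001, 300),
                            27 + rng.normal(0, 0.5, 300)])
        out = bm.stable_point_selection(np.arange(600.0), x)
        assert len(out) == 1
        assert out["time_s"].iloc[0] < 300

    def test_empty_input(self):
        assert bm.stable_point_selection([], []).empty


class TestLagDifferenceFilter:
    def test_error_propagation(self):
        f = filtered_frame([0, 600], [10.0, 10.5], [3.0, 4.0])
        ev = bm.lag_difference_filter(f)
        assert ev["sd_delta"].iloc[0] == pytest.approx(5.0)

    def test_spike_rejected_exactly(self):
        # ~unit deltas with one 10-SD excursion
        rng = np.random.default_rng(3)
        deltas = 1.0 + rng.normal(0, 0.1, 100)
        deltas[40] = 1.0 + 10 * 1.0
        values = np.concatenate([[0.0], np.cumsum(deltas)])
        f = filtered_frame(np.arange(101.0) * 600, values)
        ev = bm.lag_difference_filter(f)
        rejected = ev.index[ev["event_class"] == "rejected_outlier"].tolist()
        assert rejected == [40]

    def test_identical_deltas_none_rejected(self):
        values = np.arange(50.0) * 0.3
        ev = bm.lag_difference_filter(filtered_frame(np.arange(50.0) * 600, values))
        assert (ev["event_class"] == "rejected_outlier").sum() == 0

    def test_single_point_empty(self):
        assert bm.lag_difference_filter(filtered_frame([0.0], [1.0])).empty

    def test_false_rejection_rate_on_gaussian_deltas(self):
        """Pure Gaussian deltas should be rejected at roughly the 3-sigma
        nominal rate (~0.3% per delta) across many seeded runs."""
        total, rejected = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            values = np.concatenate([[0.0], np.cumsum(rng.normal(0, 0.05, 100))])
            ev = bm.lag_difference_filter(
                filtered_frame(np.arange(101.0) * 600, values))
            total += len(ev)
            rejected += int((ev["event_class"] == "rejected_outlier").sum())
        assert rejected / total < 0.01


class TestClassification:
    def events(self, deltas):
        return pd.DataFrame({
            "time_s": np.arange(len(deltas), dtype=float) * 600,
            "delta": np.asarray(deltas, dtype=float),
            "sd_delta": 0.01,
            "event_class": pd.array([None] * len(deltas), dtype=object)})

    def test_rule_boundaries(self):
        ev = bm.classify_mass_events(
            self.events([-0.3, -20.0, -20.001, -35.0, -35.001, 150.0]), "water")
        assert ev["event_class"].tolist() == [
            "consumption", "consumption", "body_mass_recode",
            "body_mass_recode", "refill", "refill"]

    def test_overnight_dish_sleep_recodes_mass(self):
        ev = bm.classify_mass_events(self.events([27.0, -27.0]), "food")
        assert (ev["event_class"] == "body_mass_recode").all()
        np.testing.assert_allclose(ev["mass_g"], 27.0)
        assert ev["direction"].tolist() == ["step_on", "step_off"]

    def test_perch_channel_untouched(self):
        ev = bm.classify_mass_events(self.events([-27.0]), "perch")
        assert ev["event_class"].isna().all()

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            bm.classify_mass_events(self.events([-1.0]), "seed_hopper")


class TestAggregateIntake:
    def test_hourly_consumption_sum(self):
        ev = pd.DataFrame({
            "time_s": 600.0 * np.arange(6) + 300.0,
            "delta": [-0.5] * 6, "sd_delta": 0.01,
            "event_class": "consumption", "channel": "food",
            "mass_g": np.nan})
        perch = filtered_frame([100.0], [27.0])
        out = bm.aggregate_intake(ev, perch, 3600.0)
        assert out["food_g"].iloc[0] == pytest.approx(3.0)

    def test_mass_is_mean_of_points(self):
        ev = pd.DataFrame(columns=["time_s", "delta", "sd_delta",
                                   "event_class", "channel", "mass_g"])
        perch = filtered_frame([100.0, 700.0], [26.8, 27.2])
        out = bm.aggregate_intake(ev, perch, 3600.0)
        assert out["mass_g"].iloc[0] == pytest.approx(27.0)

    def test_empty_bin_missing_mass_zero_intake(self):
        ev = pd.DataFrame(columns=["time_s", "delta", "sd_delta",
                                   "event_class", "channel", "mass_g"])
        perch = filtered_frame([100.0], [27.0])
        out = bm.aggregate_intake(ev, perch, 3600.0, span_s=(0.0, 7200.0))
        assert out["food_g"].iloc[1] == 0.0
        assert np.isnan(out["mass_g"].iloc[1])


class TestSensorDrift:
    def test_constant_channel_zero_drift(self):
        f = filtered_frame(np.arange(0, 86400.0, 600), np.full(144, 5.0))
        f["channel"] = "food"
        out = bm.sensor_drift(f)
        assert out["drift_g"].iloc[0] == 0.0

    def test_sawtooth_amplitude(self):
        t = np.arange(0, 86400.0, 600)
        f = filtered_frame(t, 0.1 + 0.1 * np.sign(np.sin(2 * np.pi * t / 7200)))
        f["channel"] = "water"
        out = bm.sensor_drift(f)
        assert out["drift_g"].iloc[0] == pytest.approx(0.2)

    def test_configured_drift_recovered_in_empty_chamber(self):
        """Noise-free empty-chamber run returns the configured per-channel
        daily drifts (perch 0.5, food 0.04, water 0.05 g/day)."""
        env = EnvironmentProgram(days=2, setpoints_c=[25.0, 25.0]).realize(0)
        truth = empty_chamber_truth(env)
        model = LoadCellModel(noise_sd_g=0.0, tare_interval_days=None)
        mt = simulate_load_cells(truth, model)
        res = bm.process_mass_trace(mt)
        drift = bm.sensor_drift(res.filtered).groupby("channel")["drift_g"].mean()
        assert drift["perch"] == pytest.approx(0.5, rel=0.02)
        assert drift["food"] == pytest.approx(0.04, rel=0.02)
        assert drift["water"] == pytest.approx(0.05, rel=0.02)


class TestEndToEnd:
    def test_data_volume_reduction_factor(self, ramp_run):
        """1 Hz input reduces ~three orders of magnitude: one stable point
        per 10 min block gives a 600-1100x reduction after filtering."""
        cfg, sim, res = ramp_run
        n_in = len(sim.mass[1].data)
        for cid in (1, 2, 3):
            filt = res.mass[cid].filtered
            for ch in ("perch", "food", "water"):
                n_out = (filt["channel"] == ch).sum()
                assert n_out <= int(np.ceil(n_in / 600))
                assert 600 <= n_in / n_out <= 1100

    def test_intake_conservation_zero_noise(self):
        """With no sensor noise or drift, recovered cumulative intake equals
        the simulator's ledger exactly."""
        env = EnvironmentProgram(days=1, setpoints_c=[25.0]).realize(1)
        bird = dataclasses.replace(BirdParams(), dish_sleep_prob=0.0).quiet()
        truth = simulate_bird_rates(bird, env, 11)
        mt = simulate_load_cells(truth, LoadCellModel.noiseless())
        res = bm.process_mass_trace(mt)
        ev = res.events
        intake_ev = ev[ev["channel"].isin(["food", "water"])]
        assert (intake_ev["event_class"] == "rejected_outlier").sum() == 0
        for ch, ledger in (("food", "food_eaten_g"), ("water", "water_drunk_g")):
            cons = ev[(ev["channel"] == ch) & (ev["event_class"] == "consumption")]
            measured = -cons["delta"].sum()
            filt = res.filtered[res.filtered["channel"] == ch]
            t0, t1 = filt["time_s"].iloc[0], filt["time_s"].iloc[-1]
            led = truth[ledger].to_numpy()
            expected = led[int(t1)] - led[int(t0)]
            assert measured == pytest.approx(expected, abs=1e-9)

    def test_dish_sleeper_mass_recovered(self):
        """A bird that sleeps on the food dish every night yields recoded
        body-mass points within noise of its true mass."""
        env = EnvironmentProgram(days=1, setpoints_c=[25.0]).realize(0)
        bird = dataclasses.replace(BirdParams(), dish_sleep_prob=1.0)
        truth = simulate_bird_rates(bird, env, 21)
        mt = simulate_load_cells(truth, LoadCellModel(), seed=2)
        res = bm.process_mass_trace(mt)
        rec = res.events[res.events["event_class"] == "body_mass_recode"]
        assert len(rec) >= 2
        np.testing.assert_allclose(rec["mass_g"], bird.body_mass_g, atol=1.0)

    def test_daily_mass_in_expected_range(self, ramp_run):
        _, _, res = ramp_run
        for cid in (1, 2, 3):
            mass = res.mass[cid].daily["mass_g"].dropna()
            assert ((mass > 23.0) & (mass < 30.3)).all()


@given(st.floats(0.0, 10.0), st.floats(0.0, 10.0))
def test_propagated_sd_is_quadrature_sum(sd1, sd2):
    f = filtered_frame([0.0, 600.0], [1.0, 1.0], [sd1, sd2])
    ev = bm.lag_difference_filter(f)
    assert ev["sd_delta"].iloc[0] == pytest.approx(np.hypot(sd1, sd2))
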
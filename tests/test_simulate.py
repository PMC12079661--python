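"""Tests for the bird-in-chamber digital twin."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import aviphen
from aviphen import simulate as sim_mod
from aviphen.params import (
    AmbientAir,
    AnalyzerModel,
    BirdParams,
    ChamberConfig,
    EnvironmentProgram,
    LoadCellModel,
    Refill,
    SamplingSchedule,
)
from aviphen.simulate import (
    empty_chamber_truth,
    simulate_bird_rates,
    simulate_chamber_washout,
    simulate_load_cells,
    simulate_multiplexed_trace,
    simulate_rfid_reads,
)


def const_env(n_seconds, temp=25.0, rh=50.0, lights=False):
    return pd.DataFrame({
        "time_s": np.arange(n_seconds, dtype=float),
        "temperature_c": np.full(n_seconds, temp),
        "rh_pct": np.full(n_seconds, rh),
        "lights_on": np.full(n_seconds, lights)})


class TestBirdRates:
    def test_thermoneutral_resting_vo2_is_bmr(self):
        bird = dataclasses.replace(BirdParams(), activity_multiplier=1.0).quiet()
        tr = simulate_bird_rates(bird, const_env(3600, temp=25.0), 0)
        np.testing.assert_allclose(tr["true_vo2"], bird.bmr_ml_o2_min)

    def test_cold_vo2_hand_value(self):
        # 10 degC below lct at conductance 0.05 on a 1.2 ml/min basal rate
        bird = dataclasses.replace(
            BirdParams(), bmr_ml_o2_min=1.2, conductance=0.05, lct_c=25.0,
            activity_multiplier=1.0).quiet()
        tr = simulate_bird_rates(bird, const_env(600, temp=15.0), 0)
        np.testing.assert_allclose(tr["true_vo2"], 1.7)
        np.testing.assert_allclose(tr["true_vco2"], 1.7 * bird.rq)

    def test_nonfinite_parameter_names_field(self):
        with pytest.raises(ValueError, match="bmr_ml_o2_min"):
            BirdParams(bmr_ml_o2_min=float("nan"))

    def test_feeding_only_during_lights_on(self):
        env = EnvironmentProgram(days=1, setpoints_c=[25.0]).realize(0)
        tr = simulate_bird_rates(BirdParams(), env, 3)
        eaten = tr["food_eaten_g"].to_numpy()
        night = ~tr["lights_on"].to_numpy()
        assert np.all(np.diff(eaten)[night[1:]] == 0)
        assert eaten[-1] > 0

    def test_deterministic_for_fixed_seed(self):
        env = const_env(7200, temp=10.0, lights=True)
        a = simulate_bird_rates(BirdParams(), env, 99)
        b = simulate_bird_rates(BirdParams(), env, 99)
        pd.testing.assert_frame_equal(a, b)


class TestChamberWashout:
    def chamber(self):
        return ChamberConfig(n_chambers=1)

    def truth_with_rates(self, n, vo2, rq=0.85, vh2o=0.0, temp=25.0, rh=0.0):
        tr = empty_chamber_truth(const_env(n, temp=temp, rh=rh))
        tr["true_vo2"] = vo2
        tr["true_vco2"] = rq * np.asarray(vo2, dtype=float)
        tr["true_vh2o"] = vh2o
        return tr

    def test_steady_state_deficit_is_vo2_over_flow(self):
        tr = self.truth_with_rates(600, 1.7)
        out = simulate_chamber_washout(tr, self.chamber(), AmbientAir())
        fio2 = 0.2095  # dry ambient; rh=0 so wet == dry
        deficit = fio2 - out["fo2"].iloc[-1]
        assert deficit == pytest.approx(1.7 / 1700.0, abs=5e-5)

    def test_step_response_is_exact_exponential(self):
        n, t0 = 4000, 500
        vo2 = np.where(np.arange(n) >= t0, 1.7, 0.0)
        tr = self.truth_with_rates(n, vo2)
        out = simulate_chamber_washout(tr, self.chamber(), AmbientAir())
        f = out["fo2"].to_numpy()
        tau = 13000.0 / 1700.0 * 60.0
        k = np.arange(n - t0)
        covered = (f[t0:] - f[t0]) / (f[-1] - f[t0])
        expected = (1 - np.exp(-k / tau)) / (1 - np.exp(-(n - 1 - t0) / tau))
        np.testing.assert_allclose(covered, expected, atol=1e-9)

    def test_zero_metabolism_outlet_equals_ambient(self):
        tr = self.truth_with_rates(600, 0.0, rh=50.0, temp=20.0)
        out = simulate_chamber_washout(tr, self.chamber(), AmbientAir())
        fio2, fico2, fh2o = sim_mod.ambient_wet_fractions(tr, AmbientAir(), 101.3)
        np.testing.assert_allclose(out["fo2"], fio2, atol=1e-12)
        np.testing.assert_allclose(out["fco2"], fico2, atol=1e-12)
        np.testing.assert_allclose(out["fh2o"], fh2o, atol=1e-12)

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError, match="flow"):
            dataclasses.replace(self.chamber(), flow_ml_min=0.0)

    def test_steady_state_mass_balance_closes(self):
        """Flow-integrated O2 deficit equals integrated true VO2 to <0.1%
        once the nitrogen-balance dilution terms are accounted for."""
        tr = self.truth_with_rates(1200, 1.5, vh2o=3.5, rh=50.0)
        cham = self.chamber()
        out = simulate_chamber_washout(tr, cham, AmbientAir())
        w = slice(600, 1200)   # steady-state window
        fh2o = out["fh2o"].to_numpy()[w]
        fe_o2 = (out["fo2"].to_numpy()[w] / (1 - fh2o)).mean()
        fe_co2 = (out["fco2"].to_numpy()[w] / (1 - fh2o)).mean()
        fre = cham.flow_ml_min * (1 - fh2o.mean())
        fri = fre * (1 - fe_o2 - fe_co2) / (1 - 0.2095 - 0.0004)
        vo2_rec = fri * 0.2095 - fre * fe_o2
        assert vo2_rec == pytest.approx(1.5, rel=1e-3)


class TestMultiplexedTrace:
    def setup_system(self, n=960):
        cham = ChamberConfig(n_chambers=2)
        env = const_env(n)
        tr1 = empty_chamber_truth(env)
        tr1["true_vo2"] = 1.5
        tr1["true_vco2"] = 1.2
        tr2 = empty_chamber_truth(env)
        chambers = {1: simulate_chamber_washout(tr1, cham, AmbientAir()),
                    2: simulate_chamber_washout(tr2, cham, AmbientAir())}
        sched = SamplingSchedule.for_chamber_config(cham)
        return cham, env, chambers, sched

    def test_marker_period_matches_schedule(self):
        cham = ChamberConfig()   # 7 chambers + baseline at 60 s
        sched = SamplingSchedule.for_chamber_config(cham)
        assert sched.cycle_period_s == 480.0
        marker = sched.slot_series(1920)
        np.testing.assert_array_equal(marker[:480], marker[480:960])
        np.testing.assert_array_equal(marker[:480], marker[960:1440])

    def test_identity_analyzer_reproduces_switched_series(self):
        cham, env, chambers, sched = self.setup_system()
        trace = simulate_multiplexed_trace(
            chambers, sched, AnalyzerModel.ideal(), env, AmbientAir(), cham, 0)
        marker = trace["marker"].to_numpy()
        for cid, df in chambers.items():
            m = marker == cid
            np.testing.assert_allclose(trace["fo2"].to_numpy()[m],
                                       df["fo2"].to_numpy()[m], atol=1e-15)

    def test_baseline_slots_report_ambient(self):
        cham, env, chambers, sched = self.setup_system()
        trace = simulate_multiplexed_trace(
            chambers, sched, AnalyzerModel.ideal(), env, AmbientAir(), cham, 0)
        m = trace["marker"].to_numpy() == 0
        fio2, _, _ = sim_mod.ambient_wet_fractions(env, AmbientAir(), cham.bp_kpa)
        np.testing.assert_allclose(trace["fo2"].to_numpy()[m], fio2[m], atol=1e-15)

    def test_unknown_chamber_rejected(self):
        cham, env, chambers, _ = self.setup_system()
        bad = SamplingSchedule([(0, 60.0), (1, 60.0), (9, 60.0)])
        with pytest.raises(ValueError, match="9"):
            simulate_multiplexed_trace(chambers, bad, AnalyzerModel.ideal(),
                                       env, AmbientAir(), cham, 0)


class TestLoadCells:
    def test_refill_is_single_positive_step(self):
        tr = empty_chamber_truth(const_env(600))
        mt = simulate_load_cells(tr, LoadCellModel.noiseless(),
                                 refills=[Refill(1, "water", 300.0, 150.0)])
        w = mt.data["water_g"].to_numpy()
        assert w[299] == pytest.approx(w[0])
        assert w[300] - w[299] == pytest.approx(150.0)
        assert np.all(np.diff(w)[np.arange(599) != 299] == 0)

    def test_quiet_bird_constant_channels(self):
        tr = empty_chamber_truth(const_env(3600))
        mt = simulate_load_cells(tr, LoadCellModel.noiseless())
        for col in ("perch_g", "food_g", "water_g"):
            assert mt.data[col].nunique() == 1

    def test_empty_chamber_daily_drift(self):
        tr = empty_chamber_truth(const_env(86400))
        model = LoadCellModel(noise_sd_g=0.0, tare_interval_days=None)
        mt = simulate_load_cells(tr, model)
        for col, rate in (("perch_g", 0.5), ("food_g", 0.04), ("water_g", 0.05)):
            x = mt.data[col].to_numpy()
            assert x.max() - x.min() == pytest.approx(rate, rel=1e-4)

    def test_consumption_ledger_matches_channel_exactly(self):
        """Before noise, cumulative channel decline equals injected intake."""
        env = EnvironmentProgram(days=1, setpoints_c=[25.0]).realize(0)
        bird = dataclasses.replace(BirdParams(), dish_sleep_prob=0.0)
        tr = simulate_bird_rates(bird, env, 5)
        mt = simulate_load_cells(tr, LoadCellModel.noiseless())
        food = mt.data["food_g"].to_numpy()
        np.testing.assert_allclose(food[0] - food,
                                   tr["food_eaten_g"].to_numpy(), atol=1e-9)

    def test_refill_outside_span_rejected(self):
        tr = empty_chamber_truth(const_env(100))
        with pytest.raises(ValueError):
            simulate_load_cells(tr, LoadCellModel.noiseless(),
                                refills=[Refill(1, "food", 1e6, 50.0)])


class TestRFID:
    def test_out_of_range_bird_yields_empty_log(self):
        tr = empty_chamber_truth(const_env(600))   # behavior = off_sensors
        reads = simulate_rfid_reads(tr, 2.0, ("perch",))
        assert reads.empty

    def test_perched_minute_gives_thirty_reads(self):
        env = const_env(60)
        tr = empty_chamber_truth(env)
        tr["behavior"] = pd.Categorical(["perch"] * 60,
                                        categories=tr["behavior"].cat.categories)
        reads = simulate_rfid_reads(tr, 2.0, ("perch",))
        assert len(reads) == 30

    def test_body_temperature_passthrough(self):
        tr = empty_chamber_truth(const_env(120))
        tr["behavior"] = pd.Categorical(["perch"] * 120,
                                        categories=tr["behavior"].cat.categories)
        tr["body_temp_c"] = 41.0
        reads = simulate_rfid_reads(tr, 2.0, ("perch",))
        assert (reads["body_temp_c"] == 41.0).all()

    def test_zero_period_rejected(self):
        with pytest.raises(ValueError):
            simulate_rfid_reads(empty_chamber_truth(const_env(10)), 0.0)


def test_fixed_seed_reproduces_every_stream():
    cfg = aviphen.ExperimentConfig(
        chamber=ChamberConfig(n_chambers=2),
        environment=EnvironmentProgram(days=1, setpoints_c=[20.0]),
        birds={1: BirdParams()})
    a = aviphen.simulate_experiment(cfg, 5)
    b = aviphen.simulate_experiment(cfg, 5)
    pd.testing.assert_frame_equal(a.gas_trace, b.gas_trace)
    pd.testing.assert_frame_equal(a.mass[1].data, b.mass[1].data)
    pd.testing.assert_frame_equal(a.rfid[1], b.rfid[1])
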
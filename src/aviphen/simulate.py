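"""Bird-in-chamber digital twin.

Generates every raw stream the real system records -- the multiplexed gas
trace, the three-channel 1 Hz load-cell logs, and the RFID body-temperature
log -- from a known ground truth, so the whole processing pipeline can be
validated without instrument data.

Model summary
-------------
* Metabolism is Scholander-type piecewise linear: VO2 = a(t)*bmr +
  c*max(0, lct - Ta), where a(t) is a circadian activity factor on the basal
  term, c the thermal conductance.  VCO2 = RQ*VO2.  Evaporative water loss
  responds multiplicatively to temperature and relative humidity.  A slow
  lognormal AR(1) adds biological hour-to-hour variability.
* The chamber is a perfectly mixed first-order washout with time constant
  tau = volume/flow; outlet fractions follow the analytic exponential update
  (zero-order-hold, not Euler), so a step response matches 1 - exp(-t/tau)
  to machine precision.
* The multiplexer switches the analyzers between chambers and an ambient
  baseline; channels then acquire transit lags, a first-order analyzer
  response, additive Gaussian noise and slow linear span drift.
* Hourly feeding/drinking totals are coupled to that hour's true energy
  expenditure and the mass leaves the dishes as a quasi-continuous trickle
  during lights-on (a sparrow pecks/licks many times a minute, which is
  unresolvable at the load-cell pipeline's 10-min cadence); behavior episodes
  (feeding/drinking visits, off-sensor spells, dish-sleep nights) are
  discrete.  Refills are large positive steps; load-cell channels drift
  linearly between tares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .params import (
    KCAL_TO_KJ,
    ML_PER_MG_H2O,
    WEIR_CO2_KCAL_PER_L,
    WEIR_O2_KCAL_PER_L,
    AmbientAir,
    AnalyzerModel,
    BirdParams,
    ChamberConfig,
    ExperimentConfig,
    LoadCellModel,
    Refill,
    SamplingSchedule,
    saturation_vapor_pressure_kpa,
)

__all__ = [
    "simulate_bird_rates",
    "empty_chamber_truth",
    "simulate_chamber_washout",
    "simulate_multiplexed_trace",
    "simulate_load_cells",
    "simulate_rfid_reads",
    "simulate_experiment",
    "MassTrace",
    "SimulatedExperiment",
]


# ---------------------------------------------------------------------------
# low-level recurrences
# ---------------------------------------------------------------------------


def _ar1_log_noise(n: int, sd: float, tau_s: float, rng) -> np.ndarray:
    """Stationary lognormal AR(1) multiplier with unit mean."""
    if sd <= 0 or n == 0:
        return np.ones(n)
    phi = math.exp(-1.0 / tau_s)
    eps = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), n)
    x0 = rng.normal(0.0, sd)
    x, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return np.exp(x - 0.5 * sd * sd)


def _washout_step(eq: np.ndarray, a: float, y0: float) -> np.ndarray:
    """Exact zero-order-hold solution of dy/dt = (eq - y)/tau at 1 Hz.

    y[n+1] = a*y[n] + (1-a)*eq[n] with a = exp(-1/tau); a step in ``eq`` at
    sample n0 is covered by exactly 1 - exp(-k/tau) after k samples.
    """
    y, _ = lfilter([0.0, 1.0 - a], [1.0, -a], eq, zi=np.array([y0]))
    return y


def _analyzer_filter(x: np.ndarray, tau_s: float) -> np.ndarray:
    """First-order analyzer response (exponential smoother; identity at tau=0)."""
    if tau_s <= 0:
        return np.asarray(x, dtype=float)
    a = math.exp(-1.0 / tau_s)
    y, _ = lfilter([1.0 - a], [1.0, -a], x, zi=np.array([a * x[0]]))
    return y


def _delay(x: np.ndarray, lag: int) -> np.ndarray:
    """Delay a series by ``lag`` whole samples, padding with its first value."""
    if lag <= 0:
        return x
    return np.concatenate([np.full(lag, x[0]), x[:-lag]])


# ---------------------------------------------------------------------------
# bird truth
# ---------------------------------------------------------------------------

_BEH_CODE = {"perch": 0, "feed": 1, "drink": 2, "on_food_dish": 3, "off_sensors": 4}
_BEH_NAME = {v: k for k, v in _BEH_CODE.items()}


def _hourly_ee_kj(vo2: np.ndarray, vco2: np.ndarray, n_hours: int) -> np.ndarray:
    """True energy expenditure per full hour (kJ) from 1 Hz rate series."""
    vo2_h = vo2[: n_hours * 3600].reshape(n_hours, 3600).sum(axis=1) / 60.0 / 1000.0
    vco2_h = vco2[: n_hours * 3600].reshape(n_hours, 3600).sum(axis=1) / 60.0 / 1000.0
    return (WEIR_O2_KCAL_PER_L * vo2_h + WEIR_CO2_KCAL_PER_L * vco2_h) * KCAL_TO_KJ


def simulate_bird_rates(params: BirdParams, env: pd.DataFrame, seed) -> pd.DataFrame:
    """Ground-truth 1 Hz record of one bird's gas exchange and behavior.

    Parameters
    ----------
    params
        Bird physiology/behavior; non-finite fields are rejected by
        :class:`~aviphen.params.BirdParams` with a message naming the field.
    env
        1 Hz environment table from
        :meth:`aviphen.params.EnvironmentProgram.realize`
        (columns ``time_s, temperature_c, rh_pct, lights_on``).
    seed
        Any :func:`numpy.random.default_rng` seed; fixed seed gives
        bit-identical output.

    Returns
    -------
    DataFrame with columns ``time_s, temperature_c, rh_pct, lights_on,
    true_vo2, true_vco2, true_vh2o`` (ml min^-1, ml min^-1, mg min^-1),
    ``behavior, body_temp_c, body_mass_g`` and cumulative ``food_eaten_g,
    water_drunk_g``.
    """
    rng = np.random.default_rng(seed)
    t = env["time_s"].to_numpy(dtype=float)
    temp = env["temperature_c"].to_numpy(dtype=float)
    rh = env["rh_pct"].to_numpy(dtype=float)
    lights = env["lights_on"].to_numpy(dtype=bool)
    n = t.size

    activity = np.where(lights, params.activity_multiplier, 1.0)
    vo2_base = activity * params.bmr_ml_o2_min + params.conductance * np.clip(
        params.lct_c - temp, 0.0, None)
    m_met = _ar1_log_noise(n, params.met_noise_sd, params.met_noise_tau_s, rng)
    vo2 = vo2_base * m_met
    vco2 = params.rq * vo2
    m_ewl = _ar1_log_noise(n, params.ewl_noise_sd, params.met_noise_tau_s, rng)
    vh2o = (params.ewl_base_mg_min
            * (1.0 + params.ewl_temp_coeff) ** (temp - 25.0)
            * (1.0 + params.ewl_rh_coeff) ** (rh - 50.0)
            * m_ewl)

    behavior = np.zeros(n, dtype=np.int8)  # perch

    # nights spent asleep on the food dish (rescued later as recoded mass)
    night_edges = np.flatnonzero(np.diff(np.concatenate(([0], (~lights).astype(int), [0]))))
    for start, stop in zip(night_edges[::2], night_edges[1::2]):
        if rng.random() < params.dish_sleep_prob:
            behavior[start:stop] = _BEH_CODE["on_food_dish"]

    n_hours = n // 3600
    ee_h = _hourly_ee_kj(vo2, vco2, n_hours)
    lights_h = lights[: n_hours * 3600].reshape(n_hours, 3600).mean(axis=1) > 0.5

    eat_rate = np.zeros(n)    # g s^-1
    drink_rate = np.zeros(n)

    def _place_bouts(hour: int, n_bouts: int, dur_s: int, code: int) -> None:
        if n_bouts < 1:
            return
        h0 = hour * 3600
        starts = np.sort(rng.integers(0, 3600 - dur_s, n_bouts)) + h0
        for s in starts:
            s = int(s)
            behavior[s:s + dur_s] = code

    for h in range(n_hours):
        if not lights_h[h]:
            continue
        food_h = params.feed_rate_g_h + params.food_ee_slope_g_kj * (
            ee_h[h] - params.ee_ref_kj)
        if params.feed_noise_sd_g > 0:
            food_h += rng.normal(0.0, params.feed_noise_sd_g)
        food_h = max(food_h, 0.0)
        water_h = params.drink_rate_g_h * math.exp(
            math.log1p(params.water_ee_effect) * (ee_h[h] - params.ee_ref_kj))
        if params.drink_noise_sd_log > 0:
            water_h *= math.exp(rng.normal(0.0, params.drink_noise_sd_log))
        # occasional short spells off every sensor
        off_dur = int(np.clip(rng.exponential(180.0), 30, 900))
        off_start = h * 3600 + int(rng.integers(0, 3600 - off_dur))
        behavior[off_start:off_start + off_dur] = _BEH_CODE["off_sensors"]
        # a sparrow removes its ~0.5 g h^-1 of ground diet in more than one
        # peck per minute and its water in small licks from the ball valve,
        # so at the sensors' effective 10-min resolution mass leaves the
        # dishes as a quasi-continuous trickle; behavior episodes stay
        # discrete for the perch and RFID channels
        eat_rate[h * 3600:(h + 1) * 3600] = food_h / 3600.0
        drink_rate[h * 3600:(h + 1) * 3600] = water_h / 3600.0
        _place_bouts(h, 8 + int(rng.poisson(4)), 30, _BEH_CODE["feed"])
        _place_bouts(h, 6 + int(rng.poisson(3)), 10, _BEH_CODE["drink"])

    food_eaten = np.cumsum(eat_rate)
    water_drunk = np.cumsum(drink_rate)

    tb_target = np.where(lights, params.tb_day_c, params.tb_night_c)
    if params.tb_noise_sd > 0:
        phi = math.exp(-1.0 / 600.0)
        eps = rng.normal(0.0, params.tb_noise_sd * math.sqrt(1 - phi * phi), n)
        x, _ = lfilter([1.0], [1.0, -phi], eps,
                       zi=np.array([phi * rng.normal(0.0, params.tb_noise_sd)]))
        tb = tb_target + x
    else:
        tb = tb_target.astype(float)

    return pd.DataFrame({
        "time_s": t,
        "temperature_c": temp,
        "rh_pct": rh,
        "lights_on": lights,
        "true_vo2": vo2,
        "true_vco2": vco2,
        "true_vh2o": vh2o,
        "behavior": pd.Categorical.from_codes(behavior, list(_BEH_CODE)),
        "body_temp_c": tb,
        "body_mass_g": np.full(n, params.body_mass_g),
        "food_eaten_g": food_eaten,
        "water_drunk_g": water_drunk,
    })


def empty_chamber_truth(env: pd.DataFrame) -> pd.DataFrame:
    """Truth record for an unoccupied chamber (zero rates, nothing on the
    sensors); used for the empty control chamber and sensor-drift checks."""
    n = len(env)
    zeros = np.zeros(n)
    return pd.DataFrame({
        "time_s": env["time_s"].to_numpy(dtype=float),
        "temperature_c": env["temperature_c"].to_numpy(dtype=float),
        "rh_pct": env["rh_pct"].to_numpy(dtype=float),
        "lights_on": env["lights_on"].to_numpy(dtype=bool),
        "true_vo2": zeros,
        "true_vco2": zeros,
        "true_vh2o": zeros,
        "behavior": pd.Categorical.from_codes(
            np.full(n, _BEH_CODE["off_sensors"], dtype=np.int8), list(_BEH_CODE)),
        "body_temp_c": zeros,
        "body_mass_g": zeros,
        "food_eaten_g": zeros,
        "water_drunk_g": zeros,
    })


# ---------------------------------------------------------------------------
# chamber gas dynamics
# ---------------------------------------------------------------------------


def ambient_wet_fractions(env: pd.DataFrame, ambient: AmbientAir,
                          bp_kpa: float):
    """Wet-air fractions of the room air entering every chamber.

    Water content follows the environmental chamber's temperature and RH
    (Tetens saturation pressure); O2/CO2 are the dry composition diluted by
    that water fraction.
    """
    rh = env["rh_pct"].to_numpy(dtype=float)
    temp = env["temperature_c"].to_numpy(dtype=float)
    fh2o = rh / 100.0 * saturation_vapor_pressure_kpa(temp) / bp_kpa
    fio2 = ambient.fio2_dry * (1.0 - fh2o)
    fico2 = ambient.fico2_dry * (1.0 - fh2o)
    return fio2, fico2, fh2o


def simulate_chamber_washout(truth: pd.DataFrame, chamber: ChamberConfig,
                             ambient: AmbientAir,
                             initial: str = "equilibrium") -> pd.DataFrame:
    """Outlet (wet) gas fractions of one perfectly mixed chamber.

    Each fraction relaxes toward its instantaneous steady state with time
    constant tau = volume/flow via the exact exponential update.  The steady
    state satisfies the full pull-mode mass balance, so at steady state the
    excurrent O2 deficit equals VO2/flow (up to the small dilution terms that
    the downstream nitrogen-balance equations account for exactly).

    ``initial='equilibrium'`` starts at the steady state of the first sample
    (a bird already resident, the usual campaign condition);
    ``initial='ambient'`` starts from a freshly flushed chamber.
    """
    if chamber.flow_ml_min <= 0:
        raise ValueError("chamber flow must be > 0: washout undefined")
    flow = chamber.flow_ml_min
    vo2 = truth["true_vo2"].to_numpy(dtype=float)
    vco2 = truth["true_vco2"].to_numpy(dtype=float)
    wv = truth["true_vh2o"].to_numpy(dtype=float) * ML_PER_MG_H2O  # ml STP min^-1

    fio2, fico2, fh2o_a = ambient_wet_fractions(truth, ambient, chamber.bp_kpa)

    fr_in = flow - wv - vco2 + vo2
    fo2_eq = (fr_in * fio2 - vo2) / flow
    fco2_eq = (fr_in * fico2 + vco2) / flow
    fh2o_eq = (fr_in * fh2o_a + wv) / flow

    # geometric tau governs the physical washout regardless of any effective
    # override used on the processing side
    tau_s = chamber.volume_l * 1000.0 / flow * 60.0
    a = math.exp(-1.0 / tau_s)

    if initial == "equilibrium":
        y0 = (fo2_eq[0], fco2_eq[0], fh2o_eq[0])
    elif initial == "ambient":
        y0 = (fio2[0], fico2[0], fh2o_a[0])
    else:
        raise ValueError("initial must be 'equilibrium' or 'ambient'")

    return pd.DataFrame({
        "time_s": truth["time_s"].to_numpy(dtype=float),
        "fo2": _washout_step(fo2_eq, a, y0[0]),
        "fco2": _washout_step(fco2_eq, a, y0[1]),
        "fh2o": _washout_step(fh2o_eq, a, y0[2]),
    })


def simulate_multiplexed_trace(chambers: Dict[int, pd.DataFrame],
                               schedule: SamplingSchedule,
                               analyzer: AnalyzerModel,
                               env: pd.DataFrame,
                               ambient: AmbientAir,
                               chamber_cfg: ChamberConfig,
                               seed,
                               flows: Optional[Dict[int, float]] = None
                               ) -> pd.DataFrame:
    """Single 1 Hz analyzer record of the multiplexed system.

    At each second the active slot's (chamber or ambient-baseline) wet
    fractions pass through per-channel transit lags, the first-order analyzer
    response, additive Gaussian noise and slow linear drift; the marker
    channel records the active slot.
    """
    missing = [c for c in schedule.chamber_ids if c not in chambers]
    if missing:
        raise ValueError(f"schedule references chambers with no series: {missing}")

    n = min(len(df) for df in chambers.values())
    n = min(n, len(env))
    marker = schedule.slot_series(n)
    rng = np.random.default_rng(seed)

    fio2_a, fico2_a, fh2o_a = ambient_wet_fractions(env.iloc[:n], ambient,
                                                    chamber_cfg.bp_kpa)
    fo2 = fio2_a.copy()
    fco2 = fico2_a.copy()
    fh2o = fh2o_a.copy()
    flow = np.full(n, chamber_cfg.flow_ml_min)
    for cid, df in chambers.items():
        mask = marker == cid
        fo2[mask] = df["fo2"].to_numpy()[:n][mask]
        fco2[mask] = df["fco2"].to_numpy()[:n][mask]
        fh2o[mask] = df["fh2o"].to_numpy()[:n][mask]
        if flows and cid in flows:
            flow[mask] = flows[cid]

    fo2 = _analyzer_filter(_delay(fo2, int(analyzer.lag_o2_s)), analyzer.response_tau_s)
    fco2 = _analyzer_filter(_delay(fco2, int(analyzer.lag_co2_h2o_s)),
                            analyzer.response_tau_s)
    fh2o = _analyzer_filter(_delay(fh2o, int(analyzer.lag_co2_h2o_s)),
                            analyzer.response_tau_s)

    t = np.arange(n, dtype=float)
    hours = t / 3600.0
    if analyzer.noise_sd_o2 > 0:
        fo2 = fo2 + rng.normal(0.0, analyzer.noise_sd_o2, n)
    if analyzer.noise_sd_co2 > 0:
        fco2 = fco2 + rng.normal(0.0, analyzer.noise_sd_co2, n)
    fo2 = fo2 + analyzer.drift_o2_per_h * hours
    fco2 = fco2 + analyzer.drift_co2_per_h * hours

    wvp = fh2o * chamber_cfg.bp_kpa
    if analyzer.noise_sd_wvp_kpa > 0:
        wvp = wvp + rng.normal(0.0, analyzer.noise_sd_wvp_kpa, n)
    wvp = wvp + analyzer.drift_wvp_kpa_per_h * hours

    return pd.DataFrame({
        "time_s": t,
        "fo2": fo2,
        "fco2": fco2,
        "wvp_kpa": wvp,
        "bp_kpa": np.full(n, chamber_cfg.bp_kpa),
        "flow_ml_min": flow,
        "marker": marker,
    })


# ---------------------------------------------------------------------------
# load cells and RFID
# ---------------------------------------------------------------------------


@dataclass
class MassTrace:
    """1 Hz three-channel load-cell record plus tare metadata."""

    data: pd.DataFrame
    tare_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    report: dict = field(default_factory=dict)


def simulate_load_cells(truth: pd.DataFrame, model: LoadCellModel,
                        refills: Sequence[Refill] = (),
                        seed=0,
                        food_initial_g: float = 30.0,
                        water_initial_g: float = 250.0) -> MassTrace:
    """Three-channel 1 Hz load-cell log for one chamber.

    The perch carries the bird's mass while it perches; the food channel
    carries remaining food (plus the bird when it sleeps on the dish) and the
    water channel remaining water.  Refills are positive steps.  Channels
    drift linearly at the configured g/day between tares and carry Gaussian
    noise.  Readings pushed below zero are clamped with a warning.
    """
    rng = np.random.default_rng(seed)
    t = truth["time_s"].to_numpy(dtype=float)
    n = t.size
    span_s = t[-1] - t[0] if n else 0.0
    beh = truth["behavior"].cat.codes.to_numpy()
    mass = truth["body_mass_g"].to_numpy(dtype=float)

    for r in refills:
        if not (t[0] <= r.time_s <= t[-1]):
            raise ValueError(f"refill at t={r.time_s} s outside the simulated span")

    if model.tare_interval_days:
        step = model.tare_interval_days * 86400.0
        tares = np.arange(t[0] + step, t[0] + span_s, step)
    else:
        tares = np.array([])

    def drift_term(rate_g_day: float) -> np.ndarray:
        if rate_g_day == 0:
            return np.zeros(n)
        last_tare = np.concatenate(([t[0]], tares))
        idx = np.searchsorted(last_tare, t, side="right") - 1
        return rate_g_day * (t - last_tare[idx]) / 86400.0

    food_level = food_initial_g - truth["food_eaten_g"].to_numpy(dtype=float)
    water_level = water_initial_g - truth["water_drunk_g"].to_numpy(dtype=float)
    for r in refills:
        level = food_level if r.channel == "food" else water_level
        level[t >= r.time_s] += r.amount_g

    perch = mass * (beh == _BEH_CODE["perch"]) + drift_term(model.drift_perch_g_day)
    food = food_level + mass * (beh == _BEH_CODE["on_food_dish"]) \
        + drift_term(model.drift_food_g_day)
    water = water_level + drift_term(model.drift_water_g_day)

    if model.noise_sd_g > 0:
        perch = perch + rng.normal(0.0, model.noise_sd_g, n)
        food = food + rng.normal(0.0, model.noise_sd_g, n)
        water = water + rng.normal(0.0, model.noise_sd_g, n)

    n_clamped = 0
    out = {}
    for name, ch in (("perch", perch), ("food", food), ("water", water)):
        neg = ch < 0
        # load-cell noise dithers around zero on empty channels; only flag
        # real negative excursions beyond noise
        bad = ch < -max(5 * model.noise_sd_g, 1e-9)
        n_clamped += int(bad.sum())
        out[name] = np.where(neg & bad, 0.0, ch)
    if n_clamped:
        warnings.warn(f"simulate_load_cells: clamped {n_clamped} negative readings")

    df = pd.DataFrame({"time_s": t, "perch_g": out["perch"],
                       "food_g": out["food"], "water_g": out["water"]})
    return MassTrace(df, tares, {"n_clamped": n_clamped})


def simulate_rfid_reads(truth: pd.DataFrame, read_period_s: float = 2.0,
                        in_range_states: Sequence[str] = ("perch",),
                        tag_id: str = "TAG-0000", seed=0) -> pd.DataFrame:
    """Sparse PIT-tag reads: one row per ``read_period_s`` whenever the bird's
    behavior places it within antenna range (~13 cm state gate)."""
    if read_period_s <= 0:
        raise ValueError("read_period_s must be > 0")
    t = truth["time_s"].to_numpy(dtype=float)
    beh = truth["behavior"].to_numpy()
    on_tick = (np.mod(t - t[0], read_period_s) == 0)
    in_range = np.isin(beh, list(in_range_states))
    sel = on_tick & in_range
    return pd.DataFrame({
        "time_s": t[sel],
        "tag": np.full(int(sel.sum()), tag_id, dtype=object),
        "body_temp_c": truth["body_temp_c"].to_numpy(dtype=float)[sel],
    })


# ---------------------------------------------------------------------------
# whole-campaign orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    """All streams of one simulated campaign plus their ground truth."""

    config: ExperimentConfig
    env: pd.DataFrame
    truth: Dict[int, pd.DataFrame]
    gas_trace: pd.DataFrame
    mass: Dict[int, MassTrace]
    rfid: Dict[int, pd.DataFrame]
    seed: int = 0

    @property
    def schedule(self) -> SamplingSchedule:
        return self.config.schedule


def simulate_experiment(config: ExperimentConfig, seed) -> SimulatedExperiment:
    """Run the full digital twin for one campaign.

    Child seeds for the environment, each bird and the analyzer are spawned
    deterministically from ``seed``, so a fixed seed reproduces every stream
    bit for bit.
    """
    ss = np.random.SeedSequence(seed)
    env_seed, trace_seed, *bird_seeds = ss.spawn(2 + config.chamber.n_chambers)
    env = config.environment.realize(env_seed)

    truth: Dict[int, pd.DataFrame] = {}
    washouts: Dict[int, pd.DataFrame] = {}
    mass: Dict[int, MassTrace] = {}
    rfid: Dict[int, pd.DataFrame] = {}
    for cid in range(1, config.chamber.n_chambers + 1):
        bird_ss = bird_seeds[cid - 1]
        s_rates, s_cells, s_rfid = bird_ss.spawn(3)
        if cid in config.birds:
            bird = config.birds[cid]
            tr = simulate_bird_rates(bird, env, s_rates)
            truth[cid] = tr
            mass[cid] = simulate_load_cells(
                tr, config.load_cell,
                [r for r in config.refills if r.chamber == cid], s_cells)
            rfid[cid] = simulate_rfid_reads(tr, tag_id=bird.tag_id, seed=s_rfid)
        else:
            tr = empty_chamber_truth(env)
            truth[cid] = tr
        washouts[cid] = simulate_chamber_washout(tr, config.chamber, config.ambient)

    gas = simulate_multiplexed_trace(
        washouts, config.schedule, config.analyzer, env, config.ambient,
        config.chamber, trace_seed)
    return SimulatedExperiment(config, env, truth, gas, mass, rfid,
                               seed=int(seed) if np.isscalar(seed) else 0)
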
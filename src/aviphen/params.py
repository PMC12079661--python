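"""Shared physical constants and configuration dataclasses.

Every tunable that the processing pipeline or the simulator uses lives here,
with the defaults of the reference system: 13-liter live-in chambers pulled at
1700 ml min^-1, seven chambers plus an ambient baseline multiplexed at 60 s
per slot, 780-g load cells logged at 1 Hz, and house-sparrow-sized birds on a
12:12 light cycle during a 25 -> 5 degC acclimation ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# physical constants
# ---------------------------------------------------------------------------

KCAL_TO_KJ = 4.184
#: Weir (protein-free) coefficients, kcal per liter of gas exchanged.
WEIR_O2_KCAL_PER_L = 3.941
WEIR_CO2_KCAL_PER_L = 1.106
#: molar volume of an ideal gas at STP, ml mol^-1
MOLAR_VOLUME_STP_ML = 22414.0
#: molar mass of water, g mol^-1
M_H2O = 18.02
#: mg of water per ml of water vapor at STP
MG_H2O_PER_ML = M_H2O * 1000.0 / MOLAR_VOLUME_STP_ML
#: ml of water vapor (STP) per mg of liquid water evaporated
ML_PER_MG_H2O = 1.0 / MG_H2O_PER_ML

#: marker value identifying ambient-baseline slots in a gas trace
BASELINE_MARKER = 0

BEHAVIORS = ("perch", "feed", "drink", "on_food_dish", "off_sensors")


def saturation_vapor_pressure_kpa(temp_c):
    """Saturation water vapor pressure (kPa) over water, Tetens formula."""
    t = np.asarray(temp_c, dtype=float)
    return 0.61078 * np.exp(17.27 * t / (t + 237.3))


def weir_kj_per_ml_o2_min(rq: float) -> float:
    """Energy yield (kJ h^-1) of 1 ml O2 min^-1 sustained for an hour.

    Follows the protein-free Weir conversion with VCO2 = rq * VO2.
    """
    return 60.0 * (WEIR_O2_KCAL_PER_L + WEIR_CO2_KCAL_PER_L * rq) * KCAL_TO_KJ / 1000.0


def conductance_for_ee_slope(slope_kj_per_degc: float, rq: float) -> float:
    """Thermal conductance (ml O2 min^-1 degC^-1) giving a target hourly-EE
    slope (kJ h^-1 per degC below the lower critical temperature)."""
    return slope_kj_per_degc / weir_kj_per_ml_o2_min(rq)


def _require_finite(obj, names: Sequence[str]) -> None:
    for name in names:
        value = getattr(obj, name)
        if value is None:
            continue
        if isinstance(value, (int, float)) and not math.isfinite(value):
            raise ValueError(f"{type(obj).__name__}.{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# hardware models
# ---------------------------------------------------------------------------


@dataclass
class ChamberConfig:
    """Geometry and plumbing of one live-in respirometry chamber."""

    volume_l: float = 13.0
    flow_ml_min: float = 1700.0
    n_chambers: int = 7
    dwell_s: float = 60.0
    baseline_dwell_s: float = 60.0
    subsample_flow_ml_min: float = 700.0
    bp_kpa: float = 101.3
    #: override for the washout time constant used by the instantaneous
    #: correction (minutes); None means the geometric volume/flow value.
    effective_tau_min: Optional[float] = None

    def __post_init__(self) -> None:
        _require_finite(self, [f.name for f in fields(self) if f.name != "n_chambers"])
        if self.volume_l <= 0:
            raise ValueError("ChamberConfig.volume_l must be > 0")
        if self.flow_ml_min <= 0:
            raise ValueError("ChamberConfig.flow_ml_min must be > 0")
        if self.dwell_s <= 0 or self.baseline_dwell_s < 0:
            raise ValueError("ChamberConfig dwell times must be positive")
        if self.n_chambers < 1:
            raise ValueError("ChamberConfig.n_chambers must be >= 1")

    @property
    def tau_min(self) -> float:
        """Washout time constant in minutes (effective override if set)."""
        if self.effective_tau_min is not None:
            return self.effective_tau_min
        return self.volume_l * 1000.0 / self.flow_ml_min

    @property
    def tau_s(self) -> float:
        return self.tau_min * 60.0

    @property
    def cycle_period_s(self) -> float:
        return self.n_chambers * self.dwell_s + self.baseline_dwell_s


@dataclass
class AnalyzerModel:
    """Gas-analyzer imperfections applied to the multiplexed sample stream.

    Lags are plumbing transit delays (O2 analyzer sits furthest downstream);
    ``response_tau_s`` is the first-order analyzer response, constrained so the
    10-90% step time (2.197 tau) stays under the 7 s instrument spec. Noise is
    additive Gaussian per channel; drift is linear in time and is what the
    interleaved ambient baselines exist to cancel.
    """

    lag_o2_s: int = 7
    lag_co2_h2o_s: int = 5
    response_tau_s: float = 3.0
    noise_sd_o2: float = 1e-6
    noise_sd_co2: float = 1e-6
    noise_sd_wvp_kpa: float = 0.002
    drift_o2_per_h: float = 1e-5
    drift_co2_per_h: float = 2e-6
    drift_wvp_kpa_per_h: float = 0.005

    def __post_init__(self) -> None:
        _require_finite(self, [f.name for f in fields(self)])
        if self.lag_o2_s < 0 or self.lag_co2_h2o_s < 0:
            raise ValueError("AnalyzerModel lags must be >= 0")
        if self.response_tau_s < 0:
            raise ValueError("AnalyzerModel.response_tau_s must be >= 0")
        if self.response_tau_s * math.log(9.0) >= 7.0:
            raise ValueError(
                "AnalyzerModel.response_tau_s too slow: 10-90% step time "
                f"{self.response_tau_s * math.log(9.0):.2f} s must be < 7 s"
            )
        for name in ("noise_sd_o2", "noise_sd_co2", "noise_sd_wvp_kpa"):
            if getattr(self, name) < 0:
                raise ValueError(f"AnalyzerModel.{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "AnalyzerModel":
        """Ideal analyzer: lags and response retained, no noise or drift."""
        return cls(noise_sd_o2=0.0, noise_sd_co2=0.0, noise_sd_wvp_kpa=0.0,
                   drift_o2_per_h=0.0, drift_co2_per_h=0.0, drift_wvp_kpa_per_h=0.0)

    @classmethod
    def ideal(cls) -> "AnalyzerModel":
        """Identity analyzer: no lag, instantaneous response, no noise/drift."""
        return cls(lag_o2_s=0, lag_co2_h2o_s=0, response_tau_s=0.0,
                   noise_sd_o2=0.0, noise_sd_co2=0.0, noise_sd_wvp_kpa=0.0,
                   drift_o2_per_h=0.0, drift_co2_per_h=0.0, drift_wvp_kpa_per_h=0.0)


@dataclass
class LoadCellModel:
    """Noise and drift of the three 1 Hz load-cell channels.

    Default daily drifts are the empty-chamber values measured for the
    reference system (perch 0.5, food 0.04, water 0.05 g day^-1). Taring
    (re-zeroing the system every couple of days) resets accumulated drift.
    """

    noise_sd_g: float = 0.03
    drift_perch_g_day: float = 0.5
    drift_food_g_day: float = 0.04
    drift_water_g_day: float = 0.05
    tare_interval_days: Optional[float] = 2.5

    def __post_init__(self) -> None:
        _require_finite(self, [f.name for f in fields(self)])
        for name in ("noise_sd_g", "drift_perch_g_day", "drift_food_g_day",
                     "drift_water_g_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"LoadCellModel.{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "LoadCellModel":
        return cls(noise_sd_g=0.0, drift_perch_g_day=0.0, drift_food_g_day=0.0,
                   drift_water_g_day=0.0, tare_interval_days=None)


# ---------------------------------------------------------------------------
# the bird
# ---------------------------------------------------------------------------

#: hourly-EE response to temperature below thermoneutrality reported for the
#: reference system, kJ h^-1 per degC; the default conductance reproduces it.
DEFAULT_EE_SLOPE_KJ_PER_DEGC = 0.05


@dataclass
class BirdParams:
    """Physiological and behavioral parameters of one simulated bird.

    The metabolic model is Scholander-type piecewise linear: below the lower
    critical temperature ``lct_c`` oxygen consumption rises linearly with
    ``conductance`` (ml O2 min^-1 degC^-1); above it the bird sits at its
    basal rate.  Activity scales the basal term during lights-on hours.
    Evaporative water loss responds multiplicatively to temperature and
    relative humidity.  Feeding and drinking are compensatory: hourly targets
    are coupled to that hour's true energy expenditure.
    """

    body_mass_g: float = 27.0
    bmr_ml_o2_min: float = 1.4
    lct_c: float = 25.0
    #: ml O2 min^-1 degC^-1 below lct; None -> derived so the hourly-EE slope
    #: equals DEFAULT_EE_SLOPE_KJ_PER_DEGC at the configured RQ.
    conductance: Optional[float] = None
    rq: float = 0.85
    #: evaporative water loss at 25 degC / 50% RH, mg min^-1
    ewl_base_mg_min: float = 3.5
    #: fractional change in EWL per +1 degC (+5% matches the reference fit)
    ewl_temp_coeff: float = 0.05
    #: fractional change in EWL per +1% RH (-4% matches the reference fit)
    ewl_rh_coeff: float = -0.04
    #: basal-metabolism multiplier during lights-on hours
    activity_multiplier: float = 1.2
    #: baseline intake rates over the 12 active hours (daily 5.7 g food and
    #: 9.4 g water at the reference EE)
    feed_rate_g_h: float = 5.7 / 12.0
    drink_rate_g_h: float = 9.4 / 12.0
    #: extra food per extra kJ of hourly EE, g kJ^-1
    food_ee_slope_g_kj: float = 0.1
    #: multiplicative effect on hourly water intake per kJ of hourly EE
    water_ee_effect: float = 0.17
    #: reference hourly EE (kJ) at which intake sits at its baseline rate
    ee_ref_kj: float = 2.0
    #: biological (AR(1), log-scale) variability of metabolic rate; modest
    #: and slow (40 min correlation) so the daily two-lowest-VO2 statistic
    #: stays in the basal range
    met_noise_sd: float = 0.06
    met_noise_tau_s: float = 2400.0
    ewl_noise_sd: float = 0.10
    #: hour-level behavioral noise of intake targets
    feed_noise_sd_g: float = 0.05
    drink_noise_sd_log: float = 0.08
    #: probability that the bird spends a given night asleep on the food dish
    dish_sleep_prob: float = 0.25
    tb_day_c: float = 41.5
    tb_night_c: float = 40.0
    tb_noise_sd: float = 0.2
    tag_id: str = "TAG-0000"

    def __post_init__(self) -> None:
        if self.conductance is None:
            self.conductance = conductance_for_ee_slope(
                DEFAULT_EE_SLOPE_KJ_PER_DEGC, self.rq)
        numeric = [f.name for f in fields(self) if f.name != "tag_id"]
        _require_finite(self, numeric)
        if self.bmr_ml_o2_min <= 0:
            raise ValueError("BirdParams.bmr_ml_o2_min must be > 0")
        if not (0.0 < self.rq <= 1.05):
            raise ValueError("BirdParams.rq must be in (0, 1.05]")
        if self.conductance < 0:
            raise ValueError("BirdParams.conductance must be >= 0")

    @property
    def ee_temp_slope_kj_per_degc(self) -> float:
        """Hourly-EE increase per degC of cooling below lct (kJ h^-1 degC^-1)."""
        return self.conductance * weir_kj_per_ml_o2_min(self.rq)

    def quiet(self) -> "BirdParams":
        """Copy with all stochastic behavior/noise switched off (oracle runs)."""
        import dataclasses
        return dataclasses.replace(
            self, met_noise_sd=0.0, ewl_noise_sd=0.0, feed_noise_sd_g=0.0,
            drink_noise_sd_log=0.0, dish_sleep_prob=0.0, tb_noise_sd=0.0)


@dataclass
class AmbientAir:
    """Dry-air composition of the incurrent (room) air."""

    fio2_dry: float = 0.2095
    fico2_dry: float = 0.0004

    def __post_init__(self) -> None:
        if not (0.0 < self.fio2_dry < 1.0) or not (0.0 <= self.fico2_dry < 0.05):
            raise ValueError("AmbientAir fractions out of range")


# ---------------------------------------------------------------------------
# environment and schedule
# ---------------------------------------------------------------------------


@dataclass
class EnvironmentProgram:
    """Temperature / humidity / lights program of the environmental chamber.

    ``setpoints_c`` holds one temperature per day; ``interp='step'`` holds each
    for its whole day (the acclimation protocol steps the chamber down daily),
    ``interp='linear'`` ramps linearly between day-start anchors. Relative
    humidity follows an hourly AR(1) around ``rh_mean`` independent of the
    temperature program. Lights are on between ``lights_on_hour`` and
    ``lights_off_hour`` each day.
    """

    days: int = 10
    setpoints_c: Optional[Sequence[float]] = None
    interp: str = "step"
    rh_mean: float = 50.0
    rh_sd: float = 5.0
    rh_phi: float = 0.7
    lights_on_hour: int = 7
    lights_off_hour: int = 19
    bp_kpa: float = 101.3
    #: thermal response of the environmental chamber (s): air temperature
    #: approaches a new setpoint first-order rather than stepping
    thermal_tau_s: float = 600.0

    def __post_init__(self) -> None:
        if self.setpoints_c is None:
            self.setpoints_c = np.linspace(25.0, 5.0, self.days)
        self.setpoints_c = tuple(float(x) for x in self.setpoints_c)
        if len(self.setpoints_c) != self.days:
            raise ValueError("EnvironmentProgram needs one setpoint per day")
        if self.interp not in ("step", "linear"):
            raise ValueError("EnvironmentProgram.interp must be 'step' or 'linear'")

    @property
    def n_seconds(self) -> int:
        return int(self.days * 86400)

    def realize(self, seed) -> "pd.DataFrame":  # noqa: F821
        """Materialize the program as a 1 Hz table (time_s, temperature_c,
        rh_pct, lights_on)."""
        import pandas as pd

        n = self.n_seconds
        t = np.arange(n, dtype=float)
        if self.interp == "step":
            temp = np.repeat(np.asarray(self.setpoints_c, dtype=float), 86400)[:n]
        else:
            anchors_t = np.arange(self.days) * 86400.0
            temp = np.interp(t, anchors_t, np.asarray(self.setpoints_c, dtype=float))
        if self.thermal_tau_s > 0:
            # first-order air-temperature response of the environmental chamber
            from scipy.signal import lfilter
            a = math.exp(-1.0 / self.thermal_tau_s)
            temp, _ = lfilter([0.0, 1.0 - a], [1.0, -a], temp,
                              zi=np.array([temp[0]]))
        rng = np.random.default_rng(seed)
        n_hours = n // 3600 + 1
        eps = rng.normal(0.0, self.rh_sd * math.sqrt(1 - self.rh_phi**2), n_hours)
        rh_h = np.empty(n_hours)
        x = rng.normal(0.0, self.rh_sd)
        for i in range(n_hours):
            x = self.rh_phi * x + eps[i]
            rh_h[i] = x
        # linear interpolation between hourly nodes: humidity drifts, it
        # does not step
        rh_nodes_t = np.arange(n_hours) * 3600.0
        rh = np.clip(self.rh_mean + np.interp(t, rh_nodes_t, rh_h), 10.0, 95.0)
        hour_of_day = (t // 3600) % 24
        lights = (hour_of_day >= self.lights_on_hour) & (hour_of_day < self.lights_off_hour)
        return pd.DataFrame({"time_s": t, "temperature_c": temp,
                             "rh_pct": rh, "lights_on": lights})


@dataclass
class SamplingSchedule:
    """The multiplexer cycle: ordered (slot_id, dwell_s) pairs.

    Slot id 0 (:data:`BASELINE_MARKER`) is the ambient baseline; other ids are
    chamber numbers.  Each chamber appears once per cycle.
    """

    slots: Sequence = ()

    def __post_init__(self) -> None:
        self.slots = tuple((int(s), float(d)) for s, d in self.slots)
        if not self.slots:
            raise ValueError("SamplingSchedule needs at least one slot")
        chambers = [s for s, _ in self.slots if s != BASELINE_MARKER]
        if len(chambers) != len(set(chambers)):
            raise ValueError("each chamber may appear only once per cycle")
        if any(d <= 0 for _, d in self.slots):
            raise ValueError("SamplingSchedule dwell times must be positive")

    @classmethod
    def cyclic(cls, n_chambers: int, dwell_s: float = 60.0,
               baseline_dwell_s: float = 60.0) -> "SamplingSchedule":
        """Baseline slot followed by each chamber in turn (the reference
        7-chamber + baseline x 60 s cycle gives one point per bird per 8 min)."""
        slots = [(BASELINE_MARKER, baseline_dwell_s)]
        slots += [(i, dwell_s) for i in range(1, n_chambers + 1)]
        return cls(slots)

    @classmethod
    def for_chamber_config(cls, chamber: ChamberConfig) -> "SamplingSchedule":
        return cls.cyclic(chamber.n_chambers, chamber.dwell_s, chamber.baseline_dwell_s)

    @property
    def cycle_period_s(self) -> float:
        return sum(d for _, d in self.slots)

    @property
    def chamber_ids(self):
        return tuple(s for s, _ in self.slots if s != BASELINE_MARKER)

    @property
    def min_dwell_s(self) -> float:
        return min(d for _, d in self.slots)

    def slot_series(self, n_seconds: int) -> np.ndarray:
        """Marker value for each of the first ``n_seconds`` 1 Hz samples."""
        one_cycle = np.concatenate(
            [np.full(int(round(d)), s, dtype=np.int64) for s, d in self.slots])
        reps = int(np.ceil(n_seconds / one_cycle.size))
        return np.tile(one_cycle, reps)[:n_seconds]


# ---------------------------------------------------------------------------
# processing thresholds and the experiment bundle
# ---------------------------------------------------------------------------


@dataclass
class ProcessingOptions:
    """Every threshold of the downstream processing pipeline, with the
    reference system's defaults."""

    # gas pipeline
    lag_o2_s: int = 7
    lag_co2_h2o_s: int = 5
    smooth_s: int = 5
    stable_final_s: int = 30
    stable_fraction: float = 0.5
    apply_instantaneous: bool = True
    # load-cell pipeline
    rolling_window_s: int = 60
    block_s: int = 600
    outlier_k: float = 3.0
    refill_threshold_g: float = 20.0
    recode_low_g: float = 20.0
    recode_high_g: float = 35.0
    #: perch readings inside this band count as the bird sitting on the perch
    mass_band_g: Sequence[float] = (15.0, 45.0)
    #: sum only negative deltas as intake (True sums net deltas instead)
    intake_net: bool = False
    # aggregation
    coverage_min: float = 0.5
    #: plausibility band for PIT-tag body temperatures, degC
    rfid_temp_band: Sequence[float] = (35.0, 45.0)

    def __post_init__(self) -> None:
        for name in ("smooth_s", "stable_final_s", "rolling_window_s", "block_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ProcessingOptions.{name} must be > 0")
        if not (0 < self.stable_fraction <= 1):
            raise ValueError("ProcessingOptions.stable_fraction must be in (0, 1]")
        if self.refill_threshold_g <= 0 or self.outlier_k <= 0:
            raise ValueError("ProcessingOptions thresholds must be positive")
        if not (self.recode_low_g <= self.recode_high_g):
            raise ValueError("ProcessingOptions recode band is inverted")
        self.mass_band_g = tuple(float(x) for x in self.mass_band_g)
        self.rfid_temp_band = tuple(float(x) for x in self.rfid_temp_band)


@dataclass
class Refill:
    """A food/water top-up: a positive step on one channel of one chamber."""

    chamber: int
    channel: str
    time_s: float
    amount_g: float

    def __post_init__(self) -> None:
        if self.channel not in ("food", "water"):
            raise ValueError("Refill.channel must be 'food' or 'water'")


@dataclass
class ExperimentConfig:
    """Complete description of one phenotyping campaign."""

    chamber: ChamberConfig = field(default_factory=ChamberConfig)
    analyzer: AnalyzerModel = field(default_factory=AnalyzerModel)
    load_cell: LoadCellModel = field(default_factory=LoadCellModel)
    environment: EnvironmentProgram = field(default_factory=EnvironmentProgram)
    ambient: AmbientAir = field(default_factory=AmbientAir)
    processing: ProcessingOptions = field(default_factory=ProcessingOptions)
    #: chamber id -> bird; chambers without an entry are simulated empty
    birds: dict = field(default_factory=dict)
    refills: Sequence[Refill] = ()

    def __post_init__(self) -> None:
        bad = [c for c in self.birds if not (1 <= int(c) <= self.chamber.n_chambers)]
        if bad:
            raise ValueError(f"bird chamber ids {bad} outside 1..{self.chamber.n_chambers}")
        self.refills = tuple(self.refills)

    @property
    def schedule(self) -> SamplingSchedule:
        return SamplingSchedule.for_chamber_config(self.chamber)

    @classmethod
    def default(cls, n_birds: int = 3, days: int = 10) -> "ExperimentConfig":
        """The reference campaign: ``n_birds`` birds in the first chambers of a
        7-chamber system, 25 -> 5 degC daily steps over ``days`` days."""
        env = EnvironmentProgram(days=days)
        birds = {i: BirdParams(tag_id=f"TAG-{i:04d}") for i in range(1, n_birds + 1)}
        refills = []
        for c in birds:
            for d in range(4, days, 4):
                refills.append(Refill(c, "food", d * 86400.0 + 8 * 3600.0, 50.0))
            for d in range(5, days, 5):
                refills.append(Refill(c, "water", d * 86400.0 + 8 * 3600.0, 150.0))
        return cls(environment=env, birds=birds, refills=refills)
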
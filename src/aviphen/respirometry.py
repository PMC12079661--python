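"""Flow-through respirometry processing for the multiplexed gas trace.

Reimplements the processing chain applied to the raw analyzer record:

1. channel lag alignment (O2 sits further downstream than CO2/H2O);
2. within-dwell smoothing and the instantaneous ("z-transform") correction
   F + tau*dF/dt that inverts the chamber's first-order washout;
3. extraction of the most stable 50% of the final 30 s of each sampling
   window (minimum-SD contiguous sub-segment);
4. water-vapor dilution correction of fractions and flow to dry values;
5. baselining against the interleaved ambient windows (linear interpolation
   in time, which cancels any affine analyzer drift exactly);
6. pull-mode gas-exchange equations.

Gas-exchange equations
----------------------
For a pull system with the flow metered on the (dried) excurrent side and
both O2 and CO2 measured, nitrogen conservation fixes the unknown incurrent
flow:

    FRi = FRe * (1 - FeO2 - FeCO2) / (1 - FiO2 - FiCO2)
    VO2  = FRi * FiO2  - FRe * FeO2
    VCO2 = FRe * FeCO2 - FRi * FiCO2

with all fractions on a dry basis and FRe the water-corrected excurrent flow.
VH2O comes from the baselined dry-basis water mixing ratio r = wvp/(bp - wvp):
VH2O [mg min^-1] = FRe * delta_r * (18.02 g mol^-1 / 22.414 l mol^-1).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import (
    BASELINE_MARKER,
    MG_H2O_PER_ML,
    AmbientAir,
    ChamberConfig,
    ProcessingOptions,
    SamplingSchedule,
)

__all__ = [
    "time_constant",
    "washout_fraction",
    "lag_align",
    "instantaneous_correct",
    "extract_stable_windows",
    "baseline_correct",
    "water_vapor_correct",
    "compute_exchange_rates",
    "process_gas_trace",
]


def time_constant(volume_l: float, flow_ml_min: float) -> float:
    """Chamber washout time constant (minutes) = volume / flow."""
    if volume_l <= 0 or flow_ml_min <= 0:
        raise ValueError("volume and flow must both be > 0")
    return volume_l * 1000.0 / flow_ml_min


def washout_fraction(elapsed_s, tau_s: float):
    """Fraction of chamber air replaced after ``elapsed_s`` under perfect
    mixing: 1 - exp(-t/tau). One time constant replaces 63.2%."""
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    elapsed = np.asarray(elapsed_s, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed time must be >= 0")
    out = 1.0 - np.exp(-elapsed / tau_s)
    return float(out) if np.isscalar(elapsed_s) else out


def lag_align(trace: pd.DataFrame, lag_o2_s: int, lag_co2_h2o_s: int) -> pd.DataFrame:
    """Shift gas channels earlier by their transit lags so every channel is
    synchronous with the marker; the common trailing samples are dropped."""
    if lag_o2_s < 0 or lag_co2_h2o_s < 0:
        raise ValueError("lags must be >= 0")
    n = len(trace)
    max_lag = int(max(lag_o2_s, lag_co2_h2o_s))
    if max_lag >= n:
        raise ValueError(f"lag {max_lag} s is not shorter than the trace ({n} s)")
    keep = n - max_lag
    out = trace.iloc[:keep].copy().reset_index(drop=True)
    lo, lc = int(lag_o2_s), int(lag_co2_h2o_s)
    out["fo2"] = trace["fo2"].to_numpy()[lo:lo + keep]
    for col, lag in (("fco2", lc), ("wvp_kpa", lc)):
        out[col] = trace[col].to_numpy()[lag:lag + keep]
    return out


def _moving_average(x: np.ndarray, window_s: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window_s <= 1:
        return np.asarray(x, dtype=float)
    s = pd.Series(x)
    return s.rolling(int(window_s), center=True, min_periods=1).mean().to_numpy()


def instantaneous_correct(values: Sequence[float], tau_s: float,
                          smoothing_window_s: int = 5) -> np.ndarray:
    """Instantaneous (z-transform) washout correction: F + tau * dF/dt.

    The derivative is taken by central differences on the smoothed series
    (one-sided at the endpoints).  Applied to the outlet of a first-order
    chamber this recovers the instantaneous input: for F(t) =
    Finf*(1 - exp(-t/tau)) the corrected series is Finf up to discretization.
    """
    x = np.asarray(values, dtype=float)
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    if x.size < max(int(smoothing_window_s), 2):
        raise ValueError("series shorter than the smoothing window")
    sm = _moving_average(x, smoothing_window_s)
    return sm + tau_s * np.gradient(sm)


def _contiguous_runs(marker: np.ndarray):
    """(start, stop, value) for each maximal run of constant marker."""
    edges = np.flatnonzero(np.diff(marker)) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [marker.size]))
    return list(zip(starts, stops, marker[starts]))


def extract_stable_windows(trace: pd.DataFrame,
                           schedule: Optional[SamplingSchedule] = None,
                           final_s: int = 30, fraction: float = 0.5,
                           select_on: str = "fo2",
                           mean_cols: Optional[Sequence[str]] = None
                           ) -> pd.DataFrame:
    """Per-dwell summary over the most stable ``fraction`` of the final
    ``final_s`` seconds of each sampling window.

    The stable segment is the contiguous sub-segment (length = fraction *
    final_s) of the final ``final_s`` samples minimizing the standard
    deviation of ``select_on`` (ties -> earliest); all channels are averaged
    over that segment.  Leading/trailing partial dwells are skipped.
    """
    if schedule is not None and schedule.min_dwell_s < final_s:
        raise ValueError(
            f"schedule dwell {schedule.min_dwell_s:.0f} s shorter than the "
            f"{final_s} s stability window")
    seg_len = int(round(final_s * fraction))
    if seg_len < 2:
        raise ValueError("stable segment must be at least 2 samples")

    marker = trace["marker"].to_numpy()
    t = trace["time_s"].to_numpy(dtype=float)
    if mean_cols is None:
        mean_cols = [c for c in trace.columns if c not in ("time_s", "marker")]
    sel = trace[select_on].to_numpy(dtype=float)

    rows = []
    runs = _contiguous_runs(marker)
    for i, (start, stop, slot) in enumerate(runs):
        if stop - start < final_s:
            continue
        # first and last runs may be truncated by the record edges
        if (i == 0 or i == len(runs) - 1) and schedule is not None:
            dwell = dict(schedule.slots).get(int(slot))
            if dwell is not None and (stop - start) < dwell:
                continue
        w0 = stop - final_s
        seg = sel[w0:stop]
        windows = np.lib.stride_tricks.sliding_window_view(seg, seg_len)
        sds = windows.std(axis=1, ddof=1)
        off = int(np.argmin(sds))  # argmin returns the earliest tie
        lo, hi = w0 + off, w0 + off + seg_len
        row = {"chamber": int(slot), "t_start": t[lo], "t_end": t[hi - 1],
               "t_mid": 0.5 * (t[lo] + t[hi - 1]), "sd_select": float(sds[off])}
        for c in mean_cols:
            row[c] = float(trace[c].to_numpy(dtype=float)[lo:hi].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def water_vapor_correct(fo2, fco2, wvp_kpa, bp_kpa, flow_ml_min):
    """Dilution correction: convert wet fractions and flow to a dry basis.

    With d = 1 - wvp/bp: dry fraction = wet fraction / d, dry flow = flow * d.
    Exact inverse of re-wetting, so the round trip is lossless.
    """
    wvp = np.asarray(wvp_kpa, dtype=float)
    bp = np.asarray(bp_kpa, dtype=float)
    if np.any(wvp < 0) or np.any(wvp >= bp):
        raise ValueError("need 0 <= wvp < bp for the dilution correction")
    d = 1.0 - wvp / bp
    return (np.asarray(fo2, dtype=float) / d,
            np.asarray(fco2, dtype=float) / d,
            np.asarray(flow_ml_min, dtype=float) * d)


def baseline_correct(samples: pd.DataFrame, baselines: pd.DataFrame,
                     channels: Sequence[str]) -> pd.DataFrame:
    """Subtract the time-interpolated ambient baseline from each sample window.

    For each sample the bracketing baseline window means are linearly
    interpolated to the sample time (edge samples use the nearest single
    baseline).  Linear interpolation cancels any affine analyzer drift
    exactly.
    """
    if len(baselines) == 0:
        raise ValueError("no baseline windows available")
    out = samples.copy()
    tb = baselines["t_mid"].to_numpy(dtype=float)
    ts = samples["t_mid"].to_numpy(dtype=float)
    order = np.argsort(tb)
    for ch in channels:
        ref = np.interp(ts, tb[order], baselines[ch].to_numpy(dtype=float)[order])
        out["d_" + ch] = samples[ch].to_numpy(dtype=float) - ref
    return out


def compute_exchange_rates(deltas: pd.DataFrame, ambient: AmbientAir) -> pd.DataFrame:
    """Pull-mode gas-exchange rates from baselined, water-corrected windows.

    Expects columns ``d_fo2_dry, d_fco2_dry, d_r`` (baselined dry fraction
    deltas and dry-basis water mixing-ratio delta) plus ``flow_dry`` and
    ``t_mid``/``chamber``.  Returns one MetabolicPoint per window: VO2/VCO2 in
    ml min^-1 via the nitrogen-balance equations, VH2O in mg min^-1 via the
    ideal-gas molar volume (18.02 g mol^-1, 22.414 l mol^-1).  VH2O is
    reported uncorrected for fecal/spilled water, as in the field protocol.
    """
    for col in ("d_fo2_dry", "d_fco2_dry", "d_r", "flow_dry"):
        vals = deltas[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in {col}")
    fi_o2, fi_co2 = ambient.fio2_dry, ambient.fico2_dry
    fe_o2 = fi_o2 + deltas["d_fo2_dry"].to_numpy(dtype=float)
    fe_co2 = fi_co2 + deltas["d_fco2_dry"].to_numpy(dtype=float)
    fre = deltas["flow_dry"].to_numpy(dtype=float)
    fri = fre * (1.0 - fe_o2 - fe_co2) / (1.0 - fi_o2 - fi_co2)
    vo2 = fri * fi_o2 - fre * fe_o2
    vco2 = fre * fe_co2 - fri * fi_co2
    vh2o = fre * deltas["d_r"].to_numpy(dtype=float) * MG_H2O_PER_ML
    return pd.DataFrame({
        "time_s": deltas["t_mid"].to_numpy(dtype=float),
        "chamber": deltas["chamber"].to_numpy(dtype=int),
        "vo2": vo2, "vco2": vco2, "vh2o": vh2o,
    })


def process_gas_trace(trace: pd.DataFrame, schedule: SamplingSchedule,
                      chamber: ChamberConfig,
                      options: Optional[ProcessingOptions] = None,
                      ambient: Optional[AmbientAir] = None,
                      taus_s: Optional[dict] = None) -> pd.DataFrame:
    """Full gas-processing chain: raw multiplexed trace -> MetabolicPoints.

    ``taus_s`` optionally overrides the washout time constant per chamber
    (effective volume may differ from geometric); by default every chamber
    uses ``chamber.tau_s``.  Smoothing and the instantaneous correction are
    applied within each dwell so switching transients cannot leak across
    marker boundaries; the correction is applied to O2 only, matching the
    field protocol.
    """
    options = options or ProcessingOptions()
    ambient = ambient or AmbientAir()

    aligned = lag_align(trace, options.lag_o2_s, options.lag_co2_h2o_s)
    marker = aligned["marker"].to_numpy()
    fo2 = aligned["fo2"].to_numpy(dtype=float).copy()
    fco2 = aligned["fco2"].to_numpy(dtype=float).copy()
    wvp = aligned["wvp_kpa"].to_numpy(dtype=float).copy()

    for start, stop, slot in _contiguous_runs(marker):
        if stop - start < max(options.smooth_s, 3):
            continue
        fco2[start:stop] = _moving_average(fco2[start:stop], options.smooth_s)
        wvp[start:stop] = _moving_average(wvp[start:stop], options.smooth_s)
        if slot != BASELINE_MARKER and options.apply_instantaneous:
            tau = (taus_s or {}).get(int(slot), chamber.tau_s)
            fo2[start:stop] = instantaneous_correct(
                fo2[start:stop], tau, options.smooth_s)
        else:
            fo2[start:stop] = _moving_average(fo2[start:stop], options.smooth_s)

    proc = aligned.copy()
    proc["fo2"], proc["fco2"], proc["wvp_kpa"] = fo2, fco2, wvp

    windows = extract_stable_windows(
        proc, schedule, final_s=options.stable_final_s,
        fraction=options.stable_fraction, select_on="fo2",
        mean_cols=["fo2", "fco2", "wvp_kpa", "bp_kpa", "flow_ml_min"])
    if windows.empty:
        return pd.DataFrame(columns=["time_s", "chamber", "vo2", "vco2", "vh2o"])

    fo2d, fco2d, flowd = water_vapor_correct(
        windows["fo2"], windows["fco2"], windows["wvp_kpa"],
        windows["bp_kpa"], windows["flow_ml_min"])
    windows = windows.assign(
        fo2_dry=fo2d, fco2_dry=fco2d, flow_dry=flowd,
        r=windows["wvp_kpa"] / (windows["bp_kpa"] - windows["wvp_kpa"]))

    is_base = windows["chamber"] == BASELINE_MARKER
    baselines = windows[is_base]
    samples = windows[~is_base]
    if samples.empty:
        return pd.DataFrame(columns=["time_s", "chamber", "vo2", "vco2", "vh2o"])
    deltas = baseline_correct(samples, baselines, ["fo2_dry", "fco2_dry", "r"])
    points = compute_exchange_rates(deltas, ambient)
    return points.sort_values("time_s", ignore_index=True)
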
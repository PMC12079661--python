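"""Load-cell biomonitoring pipeline.

The Arduino module logs perch, food-dish and water-bottle weights at 1 Hz.
This module reduces those noisy streams to stable measurements and behavioral
events:

1. per-channel 60 s centered rolling mean/SD; within every 10 min block keep
   the rolling mean with the lowest rolling SD (a ~600x data reduction);
2. lag differences between consecutive stable points with error propagation
   sd_delta = sqrt(sd_i^2 + sd_{i+1}^2), and a 3-SD outlier filter on the
   sub-threshold deltas;
3. event classification on food/water deltas: |delta| > 20 g marks refills or
   the bird perching on the dish; |delta| in (20, 35] g is recoded as a body
   mass measurement (birds sleeping on the dish); remaining negative deltas
   are consumption;
4. hourly/daily aggregation of intake (sum of consumption) and body mass
   (mean of perch readings and recoded points), plus the empty-chamber
   drift metric (daily max - min).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import ProcessingOptions
from .simulate import MassTrace

__all__ = [
    "Calibration",
    "calibrate_load_cell",
    "stable_point_selection",
    "lag_difference_filter",
    "classify_mass_events",
    "aggregate_intake",
    "sensor_drift",
    "process_mass_trace",
    "MassResult",
]

CHANNELS = ("perch", "food", "water")


@dataclass
class Calibration:
    """Counts -> grams line for one load cell, with fit quality."""

    scale_g_per_count: float
    offset_g: float
    rms_g: float

    def apply(self, counts):
        return self.scale_g_per_count * np.asarray(counts, dtype=float) + self.offset_g


def calibrate_load_cell(counts: Sequence[float],
                        reference_masses_g: Sequence[float]) -> Calibration:
    """Ordinary least squares calibration against reference weights
    (the field procedure uses 25-200 g checkweights)."""
    counts = np.asarray(counts, dtype=float)
    grams = np.asarray(reference_masses_g, dtype=float)
    if np.unique(grams).size < 2:
        raise ValueError("need at least 2 distinct reference masses")
    scale, offset = np.polyfit(counts, grams, 1)
    resid = grams - (scale * counts + offset)
    return Calibration(float(scale), float(offset), float(np.sqrt(np.mean(resid**2))))


def stable_point_selection(time_s: Sequence[float], values: Sequence[float],
                           window_s: int = 60, block_s: int = 600) -> pd.DataFrame:
    """Reduce a 1 Hz channel to at most one stable point per ``block_s``.

    Computes a centered ``window_s`` rolling mean and SD and, within each
    consecutive ``block_s`` block, keeps the rolling mean with the lowest
    rolling SD (ties -> earliest).  Blocks with no complete window are
    skipped.  Returns columns ``time_s, value, sd``.
    """
    t = np.asarray(time_s, dtype=float)
    if t.size == 0:
        return pd.DataFrame(columns=["time_s", "value", "sd"])
    s = pd.Series(np.asarray(values, dtype=float))
    roll = s.rolling(int(window_s), center=True, min_periods=int(window_s))
    mean = roll.mean().to_numpy()
    sd = roll.std().to_numpy()
    ok = np.isfinite(sd)
    if not ok.any():
        return pd.DataFrame(columns=["time_s", "value", "sd"])
    df = pd.DataFrame({"time_s": t[ok], "value": mean[ok], "sd": sd[ok],
                       "block": (t[ok] // block_s).astype(np.int64)})
    idx = df.groupby("block")["sd"].idxmin()  # first index on ties
    out = df.loc[idx, ["time_s", "value", "sd"]].reset_index(drop=True)
    return out.sort_values("time_s", ignore_index=True)


def lag_difference_filter(filtered: pd.DataFrame, k: float = 3.0,
                          classify_threshold_g: float = 20.0) -> pd.DataFrame:
    """Differences between consecutive stable points with propagated error
    and a k-SD outlier filter.

    ``sd_delta = sqrt(sd_i^2 + sd_{i+1}^2)``.  The outlier statistics (mean
    and SD of the deltas) are computed over the sub-threshold deltas
    (|delta| <= ``classify_threshold_g``) so that refill and body-mass steps
    are left for rule-based classification rather than being absorbed here;
    sub-threshold deltas farther than ``k`` SD from that mean are classed
    ``rejected_outlier``.  Each delta is stamped with the later point's time.
    """
    if len(filtered) < 2:
        return pd.DataFrame(columns=["time_s", "delta", "sd_delta", "event_class"])
    v = filtered["value"].to_numpy(dtype=float)
    sd = filtered["sd"].to_numpy(dtype=float)
    t = filtered["time_s"].to_numpy(dtype=float)
    delta = np.diff(v)
    sd_delta = np.sqrt(sd[:-1] ** 2 + sd[1:] ** 2)
    out = pd.DataFrame({"time_s": t[1:], "delta": delta, "sd_delta": sd_delta,
                        "event_class": pd.array([None] * delta.size, dtype=object)})
    small = np.abs(delta) <= classify_threshold_g
    if small.sum() >= 2:
        mu = delta[small].mean()
        sigma = delta[small].std(ddof=1)
        if sigma > 0:
            reject = small & (np.abs(delta - mu) > k * sigma)
            out.loc[reject, "event_class"] = "rejected_outlier"
    return out


def classify_mass_events(events: pd.DataFrame, channel: str,
                         refill_threshold_g: float = 20.0,
                         recode_low_g: float = 20.0,
                         recode_high_g: float = 35.0) -> pd.DataFrame:
    """Rule-based classification of food/water deltas.

    On food/water channels: |delta| in (recode_low, recode_high] is recoded
    as a body-mass measurement of |delta| grams (bird asleep on the dish,
    step-on and step-off directions both kept and flagged by sign);
    |delta| > recode_high (or any other super-threshold delta, e.g. a
    positive refill step) is a refill/perching exclusion; everything else is
    consumption.  The perch channel passes through unclassified apart from
    outliers already marked.
    """
    out = events.copy()
    if channel == "perch":
        return out
    if channel not in ("food", "water"):
        raise ValueError(f"unknown channel {channel!r}")
    d = out["delta"].to_numpy(dtype=float)
    undecided = out["event_class"].isna().to_numpy()
    mag = np.abs(d)
    recode = undecided & (mag > recode_low_g) & (mag <= recode_high_g)
    refill = undecided & (mag > recode_high_g)
    # super-threshold but sub-recode deltas only exist if the bands diverge
    refill |= undecided & (mag > refill_threshold_g) & (mag <= recode_low_g)
    consume = undecided & ~recode & ~refill
    out.loc[recode, "event_class"] = "body_mass_recode"
    out.loc[refill, "event_class"] = "refill"
    out.loc[consume, "event_class"] = "consumption"
    out["mass_g"] = np.where(recode, mag, np.nan)
    out["direction"] = np.where(recode, np.where(d > 0, "step_on", "step_off"), "")
    return out


def aggregate_intake(events: pd.DataFrame, perch_filtered: pd.DataFrame,
                     bin_s: float = 3600.0, net: bool = False,
                     mass_band_g: Sequence[float] = (15.0, 45.0),
                     span_s: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Per-bin intake and body mass for one bird.

    ``events`` holds classified deltas for the food and water channels (with
    a ``channel`` column); intake per bin is -sum of consumption deltas
    (negative-only unless ``net``).  Body mass per bin is the mean of perch
    stable points within ``mass_band_g`` (the bird actually on the perch)
    and recoded dish events.  Empty bins report 0 intake but missing mass.
    """
    lo, hi = mass_band_g
    t_candidates = [s for s in (events["time_s"], perch_filtered["time_s"])
                    if len(s)]
    t_all = (pd.concat(t_candidates, ignore_index=True).to_numpy(dtype=float)
             if t_candidates else np.array([]))
    if span_s is not None:
        t0, t1 = span_s
    elif t_all.size:
        t0, t1 = t_all.min(), t_all.max()
    else:
        return pd.DataFrame(columns=["bin_start_s", "food_g", "water_g",
                                     "mass_g", "n_mass_points"])
    edges = np.arange(np.floor(t0 / bin_s) * bin_s,
                      np.ceil((t1 + 1) / bin_s) * bin_s + 0.5 * bin_s, bin_s)
    bins = pd.DataFrame({"bin_start_s": edges[:-1]})

    def intake(channel: str) -> np.ndarray:
        ev = events[(events["channel"] == channel)
                    & (events["event_class"] == "consumption")]
        d = ev["delta"].to_numpy(dtype=float)
        if not net:
            keep = d < 0
            ev, d = ev[keep], d[keep]
        total, _ = np.histogram(ev["time_s"].to_numpy(dtype=float), bins=edges,
                                weights=-d)
        return total

    bins["food_g"] = intake("food")
    bins["water_g"] = intake("water")

    perch_ok = perch_filtered[(perch_filtered["value"] >= lo)
                              & (perch_filtered["value"] <= hi)]
    mass_t = [perch_ok["time_s"].to_numpy(dtype=float)]
    mass_v = [perch_ok["value"].to_numpy(dtype=float)]
    if "mass_g" in events.columns:
        rec = events[events["event_class"] == "body_mass_recode"]
        mass_t.append(rec["time_s"].to_numpy(dtype=float))
        mass_v.append(rec["mass_g"].to_numpy(dtype=float))
    mt = np.concatenate(mass_t)
    mv = np.concatenate(mass_v)
    n_mass, _ = np.histogram(mt, bins=edges)
    sum_mass, _ = np.histogram(mt, bins=edges, weights=mv)
    with np.errstate(invalid="ignore"):
        bins["mass_g"] = np.where(n_mass > 0, sum_mass / np.maximum(n_mass, 1), np.nan)
    bins["n_mass_points"] = n_mass
    return bins


def sensor_drift(filtered_by_channel: pd.DataFrame,
                 day_s: float = 86400.0) -> pd.DataFrame:
    """Daily drift metric (daily max - daily min of the stable points) per
    channel; the empty-chamber diagnostic. Empty days are skipped."""
    if filtered_by_channel.empty:
        return pd.DataFrame(columns=["channel", "day", "drift_g"])
    df = filtered_by_channel.assign(
        day=(filtered_by_channel["time_s"] // day_s).astype(int))
    agg = df.groupby(["channel", "day"])["value"].agg(["max", "min", "count"])
    agg = agg[agg["count"] >= 2]
    out = (agg["max"] - agg["min"]).rename("drift_g").reset_index()
    return out[["channel", "day", "drift_g"]]


@dataclass
class MassResult:
    """Products of the full load-cell pipeline for one bird."""

    filtered: pd.DataFrame   # stable points, all channels (channel column)
    events: pd.DataFrame     # classified deltas, food/water/perch
    hourly: pd.DataFrame     # aggregate_intake at 1 h bins
    daily: pd.DataFrame      # aggregate_intake at 24 h bins


def process_mass_trace(trace: MassTrace,
                       options: Optional[ProcessingOptions] = None) -> MassResult:
    """Run the whole biomonitor chain on one chamber's MassTrace.

    The record is split at tare events and deltas are taken only within
    segments, so the re-zeroing steps never masquerade as refills.
    """
    options = options or ProcessingOptions()
    data = trace.data
    t = data["time_s"].to_numpy(dtype=float)
    cuts = np.asarray(trace.tare_times_s, dtype=float)
    seg_id = np.searchsorted(cuts, t, side="right")

    filtered_frames = []
    event_frames = []
    for name in CHANNELS:
        col = f"{name}_g"
        ev_segs = []
        for seg in np.unique(seg_id):
            m = seg_id == seg
            pts = stable_point_selection(t[m], data[col].to_numpy(dtype=float)[m],
                                         options.rolling_window_s, options.block_s)
            if pts.empty:
                continue
            pts["channel"] = name
            filtered_frames.append(pts)
            ev = lag_difference_filter(pts, options.outlier_k,
                                       options.refill_threshold_g)
            ev_segs.append(ev)
        if ev_segs:
            ev = pd.concat(ev_segs, ignore_index=True)
            ev = classify_mass_events(ev, name, options.refill_threshold_g,
                                      options.recode_low_g, options.recode_high_g)
            ev["channel"] = name
            event_frames.append(ev)

    filtered = (pd.concat(filtered_frames, ignore_index=True)
                if filtered_frames else
                pd.DataFrame(columns=["time_s", "value", "sd", "channel"]))
    events = (pd.concat(event_frames, ignore_index=True)
              if event_frames else
              pd.DataFrame(columns=["time_s", "delta", "sd_delta",
                                    "event_class", "channel"]))
    perch = filtered[filtered["channel"] == "perch"]
    span = (t[0], t[-1]) if t.size else None
    hourly = aggregate_intake(events, perch, 3600.0, options.intake_net,
                              options.mass_band_g, span)
    daily = aggregate_intake(events, perch, 86400.0, options.intake_net,
                             options.mass_band_g, span)
    return MassResult(filtered, events, hourly, daily)
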
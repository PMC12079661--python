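"""Readers/writers for every stream format plus the YAML experiment config.

All interchange formats are plain text with named headers: CSV for the gas
trace, metabolic points, RFID and derived tables, and the canonical
Arduino-log dialect for the load cells (comma-delimited
``timestamp,perch_g,food_g,water_g`` rows, ISO-8601 or plain epoch-second
timestamps, tare events as ``# tare <timestamp>`` comment lines).  Writers
and readers are mutual inverses on their own output.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np
import pandas as pd
import yaml

from .params import (
    AmbientAir,
    AnalyzerModel,
    BirdParams,
    ChamberConfig,
    EnvironmentProgram,
    ExperimentConfig,
    LoadCellModel,
    ProcessingOptions,
    Refill,
)
from .simulate import MassTrace

__all__ = [
    "read_gas_trace", "write_gas_trace",
    "read_arduino_log", "write_arduino_log",
    "read_rfid_log", "write_rfid_log",
    "read_points", "write_points",
    "read_table", "write_table",
    "load_config", "save_config",
    "EPOCH",
]

#: reference wall-clock datetime for second 0 of the experiment clock (UTC)
EPOCH = _dt.datetime(2022, 1, 1, 0, 0, 0)

GAS_COLUMNS = ["time_s", "fo2", "fco2", "wvp_kpa", "bp_kpa", "flow_ml_min", "marker"]
POINT_COLUMNS = ["time_s", "chamber", "vo2", "vco2", "vh2o"]
RFID_COLUMNS = ["time_s", "tag", "body_temp_c"]


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def write_gas_trace(path, trace: pd.DataFrame) -> None:
    _check_columns(trace, GAS_COLUMNS, path)
    trace[GAS_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_gas_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, GAS_COLUMNS, path)
    for c in GAS_COLUMNS[:-1]:
        df[c] = df[c].astype(float)
    df["marker"] = df["marker"].astype(np.int64)
    return df[GAS_COLUMNS]


def write_points(path, points: pd.DataFrame) -> None:
    _check_columns(points, POINT_COLUMNS, path)
    points[POINT_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_points(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, POINT_COLUMNS, path)
    for c in ("time_s", "vo2", "vco2", "vh2o"):
        df[c] = df[c].astype(float)
    df["chamber"] = df["chamber"].astype(np.int64)
    return df[POINT_COLUMNS]


def write_table(path, table: pd.DataFrame) -> None:
    """Generic CSV writer for derived tables (hourly phenotype, events...)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Arduino load-cell log
# ---------------------------------------------------------------------------


def _fmt_ts(seconds: float) -> str:
    return (EPOCH + _dt.timedelta(seconds=float(seconds))).isoformat()


def _parse_ts(token: str) -> float:
    """Accept ISO-8601 (RTC dialect) or bare epoch/experiment seconds."""
    token = token.strip()
    try:
        return float(token)
    except ValueError:
        pass
    return (_dt.datetime.fromisoformat(token) - EPOCH).total_seconds()


def write_arduino_log(path, trace: MassTrace) -> None:
    """Canonical SD-card text layout: header, 1 Hz comma-delimited rows, and
    tare events as comment lines."""
    data = trace.data
    with open(path, "w") as fh:
        fh.write("timestamp,perch_g,food_g,water_g\n")
        for ts in np.asarray(trace.tare_times_s, dtype=float):
            fh.write(f"# tare {_fmt_ts(ts)}\n")
        t = data["time_s"].to_numpy(dtype=float)
        cols = [data[c].to_numpy(dtype=float)
                for c in ("perch_g", "food_g", "water_g")]
        for i in range(t.size):
            fh.write(f"{_fmt_ts(t[i])},{cols[0][i]:.17g},"
                     f"{cols[1][i]:.17g},{cols[2][i]:.17g}\n")


def read_arduino_log(path, max_skip_fraction: float = 0.10,
                     tare_times_s=None) -> MassTrace:
    """Parse an Arduino load-cell log.

    Unparseable rows are skipped and counted; more than
    ``max_skip_fraction`` bad rows is a hard error.  Gaps longer than 1 s
    between consecutive rows are reported in ``MassTrace.report['gaps']``.
    Tare events come from ``# tare`` comment lines or, for logs produced by
    other software, the ``tare_times_s`` argument.
    """
    times, perch, food, water = [], [], [], []
    tares = list(np.asarray(tare_times_s, dtype=float)) if tare_times_s is not None else []
    n_bad = 0
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split(None, 1)
                if parts and parts[0].lower() == "tare" and len(parts) == 2:
                    try:
                        tares.append(_parse_ts(parts[1]))
                    except ValueError:
                        n_bad += 1
                continue
            if line.lower().startswith("timestamp"):
                continue
            n_rows += 1
            fieldsep = "," if "," in line else None
            parts = line.split(fieldsep)
            try:
                if len(parts) != 4:
                    raise ValueError("wrong field count")
                times.append(_parse_ts(parts[0]))
                perch.append(float(parts[1]))
                food.append(float(parts[2]))
                water.append(float(parts[3]))
            except ValueError:
                n_bad += 1
    if n_rows == 0:
        import warnings
        warnings.warn(f"{path}: empty Arduino log")
    elif n_bad / n_rows > max_skip_fraction:
        raise ValueError(f"{path}: {n_bad}/{n_rows} unparseable rows "
                         f"(> {max_skip_fraction:.0%})")
    t = np.asarray(times, dtype=float)
    gaps = []
    if t.size > 1:
        dt = np.diff(t)
        for i in np.flatnonzero(dt > 1.5):
            gaps.append((float(t[i]), float(dt[i])))
    df = pd.DataFrame({"time_s": t, "perch_g": perch, "food_g": food,
                       "water_g": water})
    return MassTrace(df, np.asarray(sorted(tares), dtype=float),
                     {"n_skipped": n_bad, "n_rows": n_rows, "gaps": gaps})


# ---------------------------------------------------------------------------
# RFID
# ---------------------------------------------------------------------------


def write_rfid_log(path, reads: pd.DataFrame) -> None:
    _check_columns(reads, RFID_COLUMNS, path)
    reads[RFID_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_rfid_log(path, temp_band=(35.0, 45.0)) -> pd.DataFrame:
    """Read PIT-tag rows; temperatures outside the plausibility band are
    flagged (``plausible`` column), never dropped."""
    df = pd.read_csv(path)
    if df.empty and not set(RFID_COLUMNS) <= set(df.columns):
        import warnings
        warnings.warn(f"{path}: empty RFID log")
        return pd.DataFrame(columns=RFID_COLUMNS + ["plausible"])
    _check_columns(df, RFID_COLUMNS, path)
    lo, hi = temp_band
    df = df[RFID_COLUMNS].copy()
    df["time_s"] = df["time_s"].astype(float)
    df["body_temp_c"] = df["body_temp_c"].astype(float)
    df["plausible"] = (df["body_temp_c"] >= lo) & (df["body_temp_c"] <= hi)
    return df


# ---------------------------------------------------------------------------
# YAML experiment config
# ---------------------------------------------------------------------------

CONFIG_SCHEMA_VERSION = 1

_SECTIONS = {
    "chamber": ChamberConfig,
    "analyzer": AnalyzerModel,
    "load_cell": LoadCellModel,
    "environment": EnvironmentProgram,
    "ambient": AmbientAir,
    "processing": ProcessingOptions,
}


def _build_section(cls, payload: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown config key in '{section}': "
                         f"{sorted(unknown)[0]!r}")
    return cls(**payload)


def save_config(path, config: ExperimentConfig) -> None:
    doc = {"schema_version": CONFIG_SCHEMA_VERSION}
    for name, _ in _SECTIONS.items():
        doc[name] = dataclasses.asdict(getattr(config, name))
    doc["environment"]["setpoints_c"] = list(config.environment.setpoints_c)
    doc["processing"]["mass_band_g"] = list(config.processing.mass_band_g)
    doc["processing"]["rfid_temp_band"] = list(config.processing.rfid_temp_band)
    doc["birds"] = {int(cid): dataclasses.asdict(b)
                    for cid, b in config.birds.items()}
    doc["refills"] = [dataclasses.asdict(r) for r in config.refills]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    version = doc.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version}")
    known = set(_SECTIONS) | {"birds", "refills"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]!r}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in doc:
            kwargs[name] = _build_section(cls, doc[name] or {}, name)
    birds = {}
    for cid, payload in (doc.get("birds") or {}).items():
        birds[int(cid)] = _build_section(BirdParams, payload or {}, f"birds[{cid}]")
    refills = [_build_section(Refill, r, "refills") for r in doc.get("refills") or []]
    return ExperimentConfig(birds=birds, refills=refills, **kwargs)
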
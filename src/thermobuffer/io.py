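"""CSV ingestion and report writing.

One canonical dialect: comma-separated, UTF-8, header row, ISO-8601 naive
local timestamps (the loggers record Ecuadorian local time; there is no DST
so no timezone arithmetic is ever needed).

Logger CSV:   ``timestamp,temp_c[,rh_pct]``
Metadata CSV: ``logger_id,area,site_id,stratum,height_m,elevation_masl,has_humidity``
Assay CSV:    ``individual_id,group,altitude_band,sex,wing_area_mm2,
               heating_up_min,knockdown_min,censored,temp_at_ko_c
               [,development_days,egg_number]``
"""
from __future__ import annotations

import json
import logging
import os
from typing import Iterable

import pandas as pd

from .types import (
    CENSOR_MIN,
    TEMP_MAX_C,
    TEMP_MIN_C,
    AssayRecord,
    LoggerMeta,
    LoggerSeries,
    RunConfig,
)

log = logging.getLogger("thermobuffer")

# capacitive RH sensors overshoot slightly at saturation: clamp small
# overshoots, drop implausible ones
RH_CLAMP_MAX = 103.0


def read_meta_csv(path: str) -> dict[str, LoggerMeta]:
    """Read logger metadata keyed by logger_id."""
    df = pd.read_csv(path)
    metas = {}
    for row in df.itertuples(index=False):
        metas[str(row.logger_id)] = LoggerMeta(
            logger_id=str(row.logger_id),
            area=row.area,
            site_id=str(row.site_id),
            stratum=row.stratum,
            height_m=float(row.height_m),
            elevation_masl=float(row.elevation_masl),
            has_humidity=bool(row.has_humidity),
        )
    return metas


def read_logger_csv(path: str, meta: LoggerMeta) -> LoggerSeries:
    """Read one logger's hourly export.

    Rows are sorted by time; duplicate timestamps collapse to the first
    occurrence (warned).  Temperatures outside the plausibility bounds are
    dropped with a warning; RH in (100, 103] is clamped to 100, above 103
    the row is dropped.  Unparseable timestamps are a hard error naming the
    offending row.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns or "temp_c" not in df.columns:
        raise ValueError(f"{path}: need columns 'timestamp' and 'temp_c'")
    if meta.has_humidity and "rh_pct" not in df.columns:
        raise ValueError(f"{path}: humidity logger requires an 'rh_pct' column")

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna()
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(
            f"{path}: unparseable timestamp {df['timestamp'].iloc[i]!r} at row {i + 2}"
        )
    df = df.assign(timestamp=ts).sort_values("timestamp", kind="mergesort")

    ndup = int(df["timestamp"].duplicated().sum())
    if ndup:
        log.warning("%s: %d duplicate timestamps collapsed to first occurrence",
                    meta.logger_id, ndup)
        df = df[~df["timestamp"].duplicated(keep="first")]

    out_of_range = (df["temp_c"] < TEMP_MIN_C) | (df["temp_c"] > TEMP_MAX_C)
    if out_of_range.any():
        log.warning("%s: dropped %d records with temperature outside [%g, %g] °C",
                    meta.logger_id, int(out_of_range.sum()), TEMP_MIN_C, TEMP_MAX_C)
        df = df[~out_of_range]

    cols = ["timestamp", "temp_c"]
    if meta.has_humidity:
        rh = df["rh_pct"].astype(float)
        over = rh > RH_CLAMP_MAX
        if over.any():
            log.warning("%s: dropped %d records with RH > %g%%",
                        meta.logger_id, int(over.sum()), RH_CLAMP_MAX)
            df = df[~over]
            rh = rh[~over]
        clamped = rh > 100.0
        if clamped.any():
            log.warning("%s: clamped %d RH readings in (100, %g] to 100%%",
                        meta.logger_id, int(clamped.sum()), RH_CLAMP_MAX)
        df = df.assign(rh_pct=rh.clip(upper=100.0))
        cols.append("rh_pct")

    series = LoggerSeries(meta=meta, records=df[cols].reset_index(drop=True))
    gaps = series.n_gap_hours()
    if gaps:
        log.info("%s: %d missing hours in span", meta.logger_id, gaps)
    return series


def write_logger_csv(series: LoggerSeries, path: str) -> None:
    df = series.records.copy()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%d %H:%M")
    df.to_csv(path, index=False, float_format="%.4f")


_ASSAY_REQUIRED = [
    "individual_id", "group", "altitude_band", "sex", "wing_area_mm2",
    "heating_up_min", "knockdown_min", "censored", "temp_at_ko_c",
]


def read_assay_csv(path: str, group_kind: str) -> list[AssayRecord]:
    """Read heat-knockdown assay trials.

    ``group_kind`` is "species" (wild individuals) or "brood" (common-garden
    offspring; then development_days and egg_number are required).  The
    censored flag is forced true wherever the knockdown time equals the
    60-min sentinel and the file marks the individual as not knocked down.
    """
    if group_kind not in ("species", "brood"):
        raise ValueError("group_kind must be 'species' or 'brood'")
    df = pd.read_csv(path)
    required = list(_ASSAY_REQUIRED)
    if group_kind == "brood":
        required += ["development_days", "egg_number"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    records = []
    for row in df.itertuples(index=False):
        t = float(row.knockdown_min)
        if not 0 < t <= CENSOR_MIN:
            raise ValueError(
                f"{path}: knockdown_min {t} outside (0, {CENSOR_MIN}] "
                f"for individual {row.individual_id}"
            )
        records.append(AssayRecord(
            individual_id=str(row.individual_id),
            group=str(row.group),
            group_kind=group_kind,
            altitude_band=row.altitude_band,
            sex=str(row.sex),
            wing_area_mm2=float(row.wing_area_mm2),
            heating_up_min=float(row.heating_up_min),
            knockdown_min=t,
            censored=bool(row.censored),
            temp_at_ko_c=float(row.temp_at_ko_c),
            below_range=bool(getattr(row, "below_range", False)),
            development_days=float(row.development_days) if group_kind == "brood" else None,
            egg_number=float(row.egg_number) if group_kind == "brood" else None,
        ))
    return records


def write_assay_csv(records: Iterable[AssayRecord], path: str) -> None:
    rows = [r.to_dict() for r in records]
    df = pd.DataFrame(rows)
    kind = df["group_kind"].iloc[0] if len(df) else "species"
    cols = list(_ASSAY_REQUIRED)
    if kind == "brood":
        cols += ["development_days", "egg_number"]
    df[cols].to_csv(path, index=False, float_format="%.4f")


def write_report(tables: dict[str, pd.DataFrame], outdir: str,
                 config: RunConfig | None = None) -> list[str]:
    """Write each table as ``<name>.csv`` plus a JSON manifest echoing the
    run configuration and seed.  File names are deterministic; re-running
    with the same inputs produces byte-identical CSVs.
    """
    os.makedirs(outdir, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = os.path.join(outdir, f"{name}.csv")
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    # paths are environment-specific, not scientific configuration: drop
    # them so reruns elsewhere produce identical manifests
    cfg = None
    if config is not None:
        cfg = {k: v for k, v in config.to_dict().items()
               if not (k == "outdir" or k.endswith("_csv"))}
    manifest = {
        "tables": sorted(os.path.basename(p) for p in written),
        "config": cfg,
        "seed": config.seed if config is not None else None,
    }
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(mpath)
    return written
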
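"""Monthly climate statistics and bioclimatic variables from logger data.

Bio1 (annual mean temperature) is the unweighted yearly average of the
monthly averages T_avg = (T_max + T_min)/2, where T_max/T_min are monthly
means of daily extrema.  Bio2 (annual mean diurnal range) is the unweighted
yearly average of the monthly ranges (T_max − T_min); on equal-length months
this equals the annual mean of the per-day diurnal ranges exactly, and on a
real calendar year to within a few hundredths of a degree.

Interpolated macroclimate (e.g. a WorldClim2 extraction) is consumed as a
plain per-area monthly T_max/T_min table; raster handling is out of scope.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import LoggerMeta

log = logging.getLogger("thermobuffer")


def monthly_stats(dailies: pd.DataFrame) -> pd.DataFrame:
    """Monthly T_max/T_min (means of daily extrema) and T_avg per logger.

    Calendar months (1–12) are used; a record spanning 13 months pools the
    shared month.  Months with no complete days are omitted with a warning.
    """
    comp = dailies[dailies["complete"]]
    if comp.empty:
        raise ValueError("no complete days")
    g = comp.groupby(comp["date"].dt.month)
    df = g.agg(t_max=("t_max", "mean"), t_min=("t_min", "mean"),
               n_days=("t_max", "count")).reset_index(names="month")
    missing = sorted(set(range(1, 13)) - set(df["month"]))
    if missing:
        log.warning("%s: months %s have no complete days",
                    dailies["logger_id"].iloc[0], missing)
    df["t_avg"] = (df["t_max"] + df["t_min"]) / 2.0
    df.insert(0, "logger_id", dailies["logger_id"].iloc[0])
    return df


def bio1(monthly: pd.DataFrame) -> float:
    """Annual mean temperature: unweighted mean of monthly T_avg."""
    if monthly.empty:
        raise ValueError("no monthly stats")
    return float(monthly["t_avg"].mean())


def bio2(monthly: pd.DataFrame) -> float:
    """Annual mean diurnal range: unweighted mean of monthly (T_max − T_min)."""
    if monthly.empty:
        raise ValueError("no monthly stats")
    return float((monthly["t_max"] - monthly["t_min"]).mean())


def bioclim_set(monthly: pd.DataFrame, seasonality_c: float | None = None) -> dict:
    out = {"subject_id": monthly["logger_id"].iloc[0],
           "bio1": bio1(monthly), "bio2": bio2(monthly)}
    if seasonality_c is not None:
        out["seasonality"] = seasonality_c
    return out


def read_interpolated_csv(path: str) -> pd.DataFrame:
    """Read a per-area monthly interpolated-climate table.

    Columns: ``area, month, t_max, t_min``; 12 months per area required.
    """
    df = pd.read_csv(path)
    return validate_interpolated(df)


def validate_interpolated(df: pd.DataFrame) -> pd.DataFrame:
    req = {"area", "month", "t_max", "t_min"}
    if not req.issubset(df.columns):
        raise ValueError(f"interpolated table needs columns {req}")
    if df[["t_max", "t_min"]].isna().any().any():
        raise ValueError("interpolated table contains NaN temperatures")
    if df.duplicated(["area", "month"]).any():
        raise ValueError("duplicated (area, month) rows in interpolated table")
    counts = df.groupby("area")["month"].nunique()
    partial = counts[counts != 12]
    if len(partial):
        log.warning("interpolated table covers fewer than 12 months for %s",
                    list(partial.index))
    return df


def compare_to_interpolated(monthly_by_logger: dict[str, pd.DataFrame],
                            metas: dict[str, LoggerMeta],
                            interp: pd.DataFrame) -> pd.DataFrame:
    """Microclimate-minus-interpolated offsets per area × stratum.

    Logger monthly stats are first averaged within area × stratum, then
    differenced against the interpolated table month by month and averaged
    over months.  Negative offsets mean the interpolation runs warmer than
    the measured forest microclimate.
    """
    interp = validate_interpolated(interp)
    frames = []
    for lid, monthly in monthly_by_logger.items():
        meta = metas[lid]
        m = monthly.assign(area=meta.area, stratum=meta.stratum)
        frames.append(m)
    micro = (pd.concat(frames, ignore_index=True)
             .groupby(["area", "stratum", "month"], as_index=False)
             [["t_max", "t_min", "t_avg"]].mean())

    missing = set(micro["area"]) - set(interp["area"])
    if missing:
        raise ValueError(f"areas missing from interpolated table: {sorted(missing)}")

    interp = interp.assign(t_avg=(interp["t_max"] + interp["t_min"]) / 2.0)
    merged = micro.merge(interp, on=["area", "month"], suffixes=("_micro", "_interp"))
    rows = []
    for (area, stratum), grp in merged.groupby(["area", "stratum"]):
        d_max = grp["t_max_micro"] - grp["t_max_interp"]
        d_min = grp["t_min_micro"] - grp["t_min_interp"]
        d_avg = grp["t_avg_micro"] - grp["t_avg_interp"]
        rows.append({
            "area": area, "stratum": stratum,
            "offset_t_max": float(d_max.mean()),
            "offset_t_min": float(d_min.mean()),
            "offset_bio1": float(d_avg.mean()),
            "offset_bio2": float((grp["t_max_micro"] - grp["t_min_micro"]).mean()
                                 - (grp["t_max_interp"] - grp["t_min_interp"]).mean()),
            "n_months": int(len(grp)),
        })
    return pd.DataFrame(rows)
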
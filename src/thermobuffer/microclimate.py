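"""Daily/annual temperature summaries, stratum buffering and lapse rate.

The buffering of the forest interior is quantified two ways:

* **offsets** — mean over paired site-days of (subcanopy − understorey) for
  daily maxima (daytime buffering), minima (night), means and diurnal range;
* **buffering slope** — OLS slope of hourly understorey temperature on hourly
  subcanopy temperature pooled within an area: a slope below 1 means the
  understorey tracks the canopy with damped excursions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import LoggerMeta, LoggerSeries, Stratum


def daily_summaries(series: LoggerSeries, min_hours: int = 20) -> pd.DataFrame:
    """Per-calendar-date max/mean/min/diurnal range for one logger.

    Days with fewer than ``min_hours`` hourly records are flagged
    ``complete=False`` and excluded from all downstream annual statistics.
    """
    rec = series.records
    if rec.empty:
        raise ValueError("empty logger series")
    by_day = rec.groupby(rec["timestamp"].dt.normalize())["temp_c"]
    df = by_day.agg(t_max="max", t_mean="mean", t_min="min", n_hours="count")
    df = df.reset_index().rename(columns={"timestamp": "date"})
    df["diurnal_range"] = df["t_max"] - df["t_min"]
    df["complete"] = df["n_hours"] >= min_hours
    df.insert(0, "logger_id", series.meta.logger_id)
    return df[["logger_id", "date", "t_max", "t_mean", "t_min",
               "diurnal_range", "n_hours", "complete"]]


def seasonality(monthly_means) -> float:
    """Temperature seasonality: sample sd (n−1) of monthly mean temperatures.

    Reported in °C, without the ×100 scaling some bioclim products apply.
    """
    m = np.asarray(monthly_means, dtype=float)
    if m.size < 2:
        raise ValueError("seasonality needs >= 2 monthly means")
    return float(np.std(m, ddof=1))


def annual_summary(dailies: pd.DataFrame, thresholds=(30.0, 39.0)) -> dict:
    """Annual aggregates of one logger's daily summaries.

    Means are over complete days only.  ``days_above_<t>`` counts complete
    days whose maximum is strictly greater than the threshold.  Seasonality
    is the sample sd of monthly means of the daily means.
    """
    comp = dailies[dailies["complete"]]
    if comp.empty:
        raise ValueError("no complete days")
    out = {
        "logger_id": dailies["logger_id"].iloc[0],
        "mean_daily_max": float(comp["t_max"].mean()),
        "mean_daily_mean": float(comp["t_mean"].mean()),
        "mean_daily_min": float(comp["t_min"].mean()),
        "mean_diurnal_range": float(comp["diurnal_range"].mean()),
        "n_days_used": int(len(comp)),
    }
    monthly = comp.groupby(comp["date"].dt.to_period("M"))["t_mean"].mean()
    out["seasonality"] = seasonality(monthly.to_numpy()) if len(monthly) >= 2 else np.nan
    for thr in thresholds:
        out[f"days_above_{thr:g}"] = int((comp["t_max"] > thr).sum())
    return out


def annual_summaries(dailies_by_logger: dict[str, pd.DataFrame],
                     thresholds=(30.0, 39.0)) -> pd.DataFrame:
    """One annual-summary row per logger."""
    return pd.DataFrame([
        annual_summary(d, thresholds) for d in dailies_by_logger.values()
    ])


_OFFSET_STATS = {"daily_max": "t_max", "daily_mean": "t_mean",
                 "daily_min": "t_min", "diurnal_range": "diurnal_range"}


def stratum_offsets(dailies_by_logger: dict[str, pd.DataFrame],
                    metas: dict[str, LoggerMeta]) -> pd.DataFrame:
    """Understorey temperature offsets (subcanopy − understorey) per area.

    For every site with a logger in each stratum, complete days present in
    both loggers are paired by date; the offset for each statistic is the
    mean over all paired site-days in the area, with its standard error.
    A positive daily-max offset means the understorey stays cooler than the
    subcanopy during the day.
    """
    per_site = {}
    for lid, meta in metas.items():
        if lid in dailies_by_logger:
            per_site.setdefault((meta.area, meta.site_id), {})[meta.stratum] = \
                dailies_by_logger[lid]

    diffs: dict[str, dict[str, list]] = {}
    for (area, _site), strata in per_site.items():
        if len(strata) < 2:
            continue
        sub = strata[Stratum.SUBCANOPY.value]
        und = strata[Stratum.UNDERSTOREY.value]
        merged = pd.merge(sub[sub["complete"]], und[und["complete"]],
                          on="date", suffixes=("_sub", "_und"))
        if merged.empty:
            continue
        for stat, col in _OFFSET_STATS.items():
            d = (merged[f"{col}_sub"] - merged[f"{col}_und"]).to_numpy()
            diffs.setdefault(area, {}).setdefault(stat, []).append(d)

    rows = []
    for area, stats_ in diffs.items():
        for stat, arrays in stats_.items():
            d = np.concatenate(arrays)
            rows.append({
                "area": area, "statistic": stat,
                "offset_c": float(d.mean()),
                "se": float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan,
                "n_pairs": int(len(d)),
            })
    if not rows:
        import logging
        logging.getLogger("thermobuffer").warning("no paired site-days found")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BufferingSlope:
    """OLS fit of hourly understorey temperature on subcanopy temperature."""

    area: str
    slope: float
    intercept: float
    se: float
    r2: float
    n_hours: int


def align_strata_hours(sub: LoggerSeries, und: LoggerSeries) -> pd.DataFrame:
    """Inner-join two hourly series on timestamp → columns t_sub, t_und."""
    m = pd.merge(sub.records[["timestamp", "temp_c"]],
                 und.records[["timestamp", "temp_c"]],
                 on="timestamp", suffixes=("_sub", "_und"))
    return m.rename(columns={"temp_c_sub": "t_sub", "temp_c_und": "t_und"})


def buffering_slope(aligned: pd.DataFrame, area: str = "") -> BufferingSlope:
    """Slope of understorey on subcanopy over pooled aligned hours."""
    if len(aligned) < 2:
        raise ValueError("need >= 2 aligned hours")
    x = aligned["t_sub"].to_numpy()
    y = aligned["t_und"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero variance in subcanopy temperatures")
    fit = stats.linregress(x, y)
    return BufferingSlope(area=area, slope=float(fit.slope),
                          intercept=float(fit.intercept),
                          se=float(fit.stderr), r2=float(fit.rvalue ** 2),
                          n_hours=int(len(aligned)))


def buffering_slopes_by_area(series_by_logger: dict[str, LoggerSeries],
                             metas: dict[str, LoggerMeta]) -> pd.DataFrame:
    """Pool site pairs within each area and fit one slope per area."""
    per_site: dict[tuple, dict] = {}
    for lid, meta in metas.items():
        if lid in series_by_logger:
            per_site.setdefault((meta.area, meta.site_id), {})[meta.stratum] = \
                series_by_logger[lid]
    pooled: dict[str, list[pd.DataFrame]] = {}
    for (area, _site), strata in per_site.items():
        if len(strata) == 2:
            pooled.setdefault(area, []).append(
                align_strata_hours(strata[Stratum.SUBCANOPY.value],
                                   strata[Stratum.UNDERSTOREY.value]))
    rows = []
    for area, frames in pooled.items():
        fit = buffering_slope(pd.concat(frames, ignore_index=True), area=area)
        rows.append(vars(fit))
    return pd.DataFrame(rows)


def lapse_rate(annual: pd.DataFrame, metas: dict[str, LoggerMeta]) -> dict:
    """OLS slope of per-logger annual mean temperature on elevation.

    Returns the rate in °C per metre and per 10 m (the scale on which Andean
    elevational clines are usually quoted).
    """
    elev = annual["logger_id"].map(lambda lid: metas[lid].elevation_masl)
    if elev.nunique() < 2:
        raise ValueError("need >= 2 distinct elevations")
    fit = stats.linregress(elev.to_numpy(dtype=float),
                           annual["mean_daily_mean"].to_numpy())
    return {"slope_c_per_m": float(fit.slope),
            "slope_c_per_10m": float(10 * fit.slope),
            "se": float(fit.stderr), "r2": float(fit.rvalue ** 2),
            "n": int(len(annual))}


def group_comparison(values_by_group: dict[str, np.ndarray],
                     design: str = "two-group") -> pd.DataFrame:
    """Compare group means.

    ``two-group``: pooled-variance Student t (df = n1 + n2 − 2), two-sided.
    ``pairwise-all``: Tukey HSD over the one-way layout (studentized range).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.ptp(v) == 0 for v in groups.values()):
        raise ValueError("zero within-group variance in all groups")

    if design == "two-group":
        if len(groups) != 2:
            raise ValueError("two-group design needs exactly 2 groups")
        (na, a), (nb, b) = groups.items()
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return pd.DataFrame([{
            "group_a": na, "group_b": nb, "t": float(t),
            "df": len(a) + len(b) - 2, "p": float(p),
            "mean_diff": float(a.mean() - b.mean()),
        }])
    if design == "pairwise-all":
        names = list(groups)
        res = stats.tukey_hsd(*groups.values())
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append({
                    "group_a": names[i], "group_b": names[j],
                    "mean_diff": float(groups[names[i]].mean()
                                       - groups[names[j]].mean()),
                    "p": float(res.pvalue[i, j]),
                })
        return pd.DataFrame(rows)
    raise ValueError(f"unknown design {design!r}")
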
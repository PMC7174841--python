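"""Vapour pressure deficit from coupled hourly temperature/RH records.

VPD (hPa) is the gap between the saturation water vapour pressure e_s(T) and
the actual vapour pressure e = e_s * RH/100 — the "drying power" of the air.
Saturation vapour pressure uses Bolton's (1980) empirical fit

    e_s(T) = 6.112 * exp(17.67 T / (T + 243.5))   [hPa, T in °C]

accurate to ~0.1% over -30..35 °C.  The classic Magnus coefficients
(6.1094, 17.625, 243.04) are available via ``formula="magnus"``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import TEMP_MAX_C, TEMP_MIN_C, LoggerSeries

_COEFFS = {
    "bolton": (6.112, 17.67, 243.5),
    "magnus": (6.1094, 17.625, 243.04),
}


def saturation_vp(temp_c, formula: str = "bolton"):
    """Saturation vapour pressure e_s (hPa) at temperature ``temp_c`` (°C).

    Accepts scalars or arrays; temperatures outside the logger plausibility
    bounds [-10, 55] °C are a hard error.
    """
    a, b, c = _COEFFS[formula]
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < TEMP_MIN_C) or np.any(t > TEMP_MAX_C):
        raise ValueError(f"temperature outside [{TEMP_MIN_C}, {TEMP_MAX_C}] °C")
    es = a * np.exp(b * t / (t + c))
    return float(es) if np.isscalar(temp_c) else es


def vpd(temp_c, rh_percent, formula: str = "bolton"):
    """Vapour pressure deficit (hPa): e_s(T) * (1 - RH/100).

    Zero when the air is saturated (RH=100); equals e_s when bone dry.
    """
    rh = np.asarray(rh_percent, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity outside [0, 100] %")
    out = saturation_vp(temp_c, formula=formula) * (1.0 - rh / 100.0)
    return float(out) if np.isscalar(temp_c) and np.isscalar(rh_percent) else out


def vpd_series(series: LoggerSeries, formula: str = "bolton") -> pd.DataFrame:
    """Hourly VPD for every coupled (T, RH) observation of one logger.

    Coupled means the same logger and hour; no interpolation is done.
    Returns columns ``timestamp, vpd_hpa``.
    """
    if not series.meta.has_humidity:
        raise ValueError(f"logger {series.meta.logger_id} has no humidity channel")
    rec = series.records
    return pd.DataFrame({
        "timestamp": rec["timestamp"],
        "vpd_hpa": vpd(rec["temp_c"].to_numpy(), rec["rh_pct"].to_numpy(),
                       formula=formula),
    })


def vpd_summaries(hourly: pd.DataFrame, thresholds=(12.0,),
                  min_hours: int = 20) -> dict:
    """Annual VPD summary of one logger's hourly VPD table.

    * ``vpd_mean`` — mean over all hourly records;
    * ``vpd_max`` — mean of per-day maxima over complete days (>= min_hours
      records in the day);
    * ``n_exceed_<thr>`` — hourly records strictly above each threshold
      (default 12 hPa, the level above which tree transpiration in tropical
      montane forest is thought to be impeded).
    """
    if hourly.empty:
        raise ValueError("empty VPD series")
    v = hourly["vpd_hpa"]
    out = {"vpd_mean": float(v.mean())}
    by_day = hourly.groupby(hourly["timestamp"].dt.normalize())["vpd_hpa"]
    daily = by_day.agg(["max", "count"])
    complete = daily[daily["count"] >= min_hours]
    out["vpd_max"] = float(complete["max"].mean()) if len(complete) else float(v.max())
    out["n_days_used"] = int(len(complete))
    for thr in thresholds:
        out[f"n_exceed_{thr:g}"] = int((v > thr).sum())
    return out
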
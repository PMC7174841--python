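"""Synthetic logger networks, interpolated-climate tables and assay data.

The generator emulates the study design the analyses assume: four areas
(elevation band × Andean slope), ~7 paired-logger forest sites per area,
one full year of hourly records, low seasonality, larger diurnal cycles in
the lowland subcanopy, an understorey linearly coupled to the subcanopy with
a slope below one, relative humidity anticorrelated with temperature, and
heat-knockdown times driven by a random-intercept model with an altitude
effect.

Every quantity a downstream estimator recovers (baseline contrasts,
buffering slope, lapse rate, interpolation bias, variance components,
fixed effects) is an explicit parameter, so generative-recovery tests can
compare estimates against known truth.  Fixed seed ⇒ bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import AREAS, AssayRecord, LoggerMeta, LoggerSeries, area_altitude


@dataclass(frozen=True)
class AreaClimate:
    """Climate truth for one study area.

    ``baseline_c`` is the annual mean subcanopy temperature; the seasonal and
    diurnal harmonics are half-ranges (max − mean).  The understorey is
    ``intercept_c + slope_b × subcanopy + noise``; the implied mean stratum
    offset is ``(1 − slope_b)·baseline_c − intercept_c``.
    """

    baseline_c: float
    elevation_masl: float
    seasonal_amp_c: float
    diurnal_amp_c: float
    slope_b: float
    intercept_c: float

    def __post_init__(self) -> None:
        if not 0 < self.slope_b <= 1.2:
            raise ValueError("slope_b must be in (0, 1.2]")
        if self.seasonal_amp_c < 0 or self.diurnal_amp_c < 0:
            raise ValueError("amplitudes must be >= 0")


def area_climate(baseline_c: float, elevation_masl: float,
                 seasonal_amp_c: float, diurnal_amp_c: float,
                 slope_b: float, mean_offset_c: float) -> AreaClimate:
    """Build an AreaClimate from a target mean stratum offset (subcanopy −
    understorey) instead of a raw coupling intercept."""
    intercept = (1.0 - slope_b) * baseline_c - mean_offset_c
    return AreaClimate(baseline_c, elevation_masl, seasonal_amp_c,
                       diurnal_amp_c, slope_b, intercept)


@dataclass
class MicroclimateSimParams:
    """Study-condition defaults: 4.1 °C lowland–highland baseline gap,
    buffering slopes 0.68 (lowlands) / 0.73 (highlands), mean stratum
    offsets 0.44 / 0.25 °C, low seasonality (sd of monthly means ≈ 0.63),
    −0.005 °C/m lapse across the site elevations."""

    areas: dict = field(default_factory=lambda: {
        "west-low": area_climate(24.5, 495.0, 0.9, 5.0, 0.68, 0.44),
        "east-low": area_climate(24.5, 445.0, 0.9, 5.0, 0.68, 0.44),
        "west-high": area_climate(20.4, 1315.0, 0.9, 3.5, 0.73, 0.25),
        "east-high": area_climate(20.4, 1265.0, 0.9, 3.5, 0.73, 0.25),
    })
    sites_per_area: int = 7
    humidity_sites_per_area: int = 2
    n_days: int = 365
    year_start: str = "2017-02-01"
    diurnal_peak_hour: float = 13.0
    seasonal_peak_day: float = 330.0       # day-of-year of warmest month
    ar_coef: float = 0.7                   # hourly AR(1) of subcanopy noise
    ar_sd_c: float = 0.8                   # marginal sd of that noise
    understorey_noise_sd_c: float = 0.4    # white noise around the coupling
    site_sd_c: float = 0.3                 # between-site baseline offsets
    site_elev_jitter_m: float = 25.0
    lapse_c_per_m: float = -0.005
    rh_base_pct: float = 93.0
    rh_coupling_pct_per_c: float = 3.5
    rh_noise_sd_pct: float = 1.5
    seed: int = 12345

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coef <= 0.99:
            raise ValueError("ar_coef must be in [0, 0.99]")
        for name in ("ar_sd_c", "understorey_noise_sd_c", "site_sd_c",
                     "rh_noise_sd_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.areas) - set(AREAS)
        if unknown:
            raise ValueError(f"unknown areas {sorted(unknown)}")


def _ar1(rng: np.random.Generator, n: int, coef: float, sd: float) -> np.ndarray:
    """AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - coef ** 2)
    e = rng.normal(0.0, innov_sd, n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = coef * out[t - 1] + e[t]
    return out


def gen_microclimate(params: MicroclimateSimParams
                     ) -> tuple[dict[str, LoggerMeta], dict[str, LoggerSeries]]:
    """Generate the paired understorey/subcanopy logger network.

    Returns (metas, series) keyed by logger_id.  Subcanopy temperature is
    baseline + seasonal harmonic + diurnal harmonic + AR(1) noise; the
    understorey is the linear coupling plus independent white noise,
    hour-aligned.  RH is ``clip(base − c·(T − site baseline) + noise, 5, 100)``
    on the loggers that carry a humidity channel.
    """
    rng = np.random.default_rng(params.seed)
    n_hours = params.n_days * 24
    ts = pd.date_range(params.year_start, periods=n_hours, freq="h")
    hour = ts.hour.to_numpy(dtype=float)
    doy = ts.dayofyear.to_numpy(dtype=float)
    diurnal_shape = np.cos(2 * np.pi * (hour - params.diurnal_peak_hour) / 24.0)
    seasonal_shape = np.cos(2 * np.pi * (doy - params.seasonal_peak_day) / 365.25)

    metas: dict[str, LoggerMeta] = {}
    series: dict[str, LoggerSeries] = {}
    for area, clim in params.areas.items():
        # site offsets are centred within the area so the configured
        # baseline is the exact area mean, not just its expectation
        offsets = rng.normal(0.0, params.site_sd_c, params.sites_per_area)
        if params.sites_per_area > 1:
            offsets -= offsets.mean()
        for s in range(params.sites_per_area):
            site_id = f"{area}-s{s + 1}"
            elev = clim.elevation_masl + rng.uniform(
                -params.site_elev_jitter_m, params.site_elev_jitter_m)
            base = (clim.baseline_c
                    + params.lapse_c_per_m * (elev - clim.elevation_masl)
                    + offsets[s])
            t_sub = (base
                     + clim.seasonal_amp_c * seasonal_shape
                     + clim.diurnal_amp_c * diurnal_shape
                     + _ar1(rng, n_hours, params.ar_coef, params.ar_sd_c))
            t_und = (clim.intercept_c + clim.slope_b * t_sub
                     + rng.normal(0.0, params.understorey_noise_sd_c, n_hours))
            has_rh = s < params.humidity_sites_per_area
            for stratum, temps, height in (
                    ("subcanopy", t_sub, float(rng.normal(10.7, 1.5))),
                    ("understorey", t_und, float(rng.normal(1.16, 0.3)))):
                lid = f"{site_id}-{stratum[:3]}"
                meta = LoggerMeta(logger_id=lid, area=area, site_id=site_id,
                                  stratum=stratum,
                                  height_m=float(np.clip(height, 0.2, 39.0)),
                                  elevation_masl=float(elev),
                                  has_humidity=has_rh)
                rec = pd.DataFrame({"timestamp": ts, "temp_c": temps})
                if has_rh:
                    rh = (params.rh_base_pct
                          - params.rh_coupling_pct_per_c * (temps - base)
                          + rng.normal(0.0, params.rh_noise_sd_pct, n_hours))
                    rec["rh_pct"] = np.clip(rh, 5.0, 100.0)
                metas[lid] = meta
                series[lid] = LoggerSeries(meta=meta, records=rec)
    return metas, series


def gen_interpolated_table(series: dict[str, LoggerSeries],
                           metas: dict[str, LoggerMeta],
                           bias: dict | None = None,
                           min_hours: int = 20) -> pd.DataFrame:
    """Per-area monthly T_max/T_min table emulating a macroclimate extraction.

    The truth is the simulated subcanopy climate (monthly means of daily
    extrema averaged across an area's subcanopy loggers); ``bias`` maps
    area → {"t_max": Δ, "t_min": Δ} offsets added on top, e.g. +2.01 °C on
    highland maxima to emulate an interpolation that runs warm.
    """
    from .microclimate import daily_summaries
    from .bioclim import monthly_stats

    frames = []
    for lid, ser in series.items():
        if metas[lid].stratum != "subcanopy":
            continue
        m = monthly_stats(daily_summaries(ser, min_hours=min_hours))
        frames.append(m.assign(area=metas[lid].area))
    tbl = (pd.concat(frames, ignore_index=True)
           .groupby(["area", "month"], as_index=False)[["t_max", "t_min"]]
           .mean())
    if bias:
        for area, b in bias.items():
            if any(v is None or (isinstance(v, float) and math.isnan(v))
                   for v in b.values()):
                raise ValueError(f"NaN bias for area {area}")
            sel = tbl["area"] == area
            tbl.loc[sel, "t_max"] += b.get("t_max", 0.0)
            tbl.loc[sel, "t_min"] += b.get("t_min", 0.0)
    tbl["provenance"] = "synthetic-interpolation"
    return tbl


# --------------------------------------------------------------------------
# assays


@dataclass
class AssaySimParams:
    """Heat-knockdown assay generator.

    Variance components and effects are stated in minutes on the analysis
    scale; the noise is drawn on the log scale (scaled by the mean
    deterministic predictor) so times stay positive while the minute-scale
    components are preserved to first order.  Defaults mirror the wild
    survey: 10 species sampled at two elevations, highland mean knockdown
    ≈ 5.4 min, lowlanders lasting ≈ 10.5 min longer, pre-39 °C knockdown
    probabilities 0.33 (high) / 0.07 (low), censoring at 60 min.
    """

    n_groups: int = 10
    n_per_group_band: int = 14
    group_kind: str = "species"
    baseline_min: float = 5.4              # mean knockdown, high band
    altitude_effect_min: float = 10.5      # low minus high
    group_sd_min: float = 3.1
    resid_sd_min: float = 7.6
    beta_heating_min_per_min: float = 0.0
    beta_temp_ko_min_per_c: float = 0.0
    beta_wing_min_per_mm2: float = 0.0
    pre39_prob_high: float = 0.33
    pre39_prob_low: float = 0.07
    censor_horizon_min: float = 60.0
    bands: tuple = ("high", "low")
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.group_sd_min < 0 or self.resid_sd_min < 0:
            raise ValueError("sds must be >= 0")
        for p in (self.pre39_prob_high, self.pre39_prob_low):
            if not 0 <= p <= 1:
                raise ValueError("pre-39 probabilities must be in [0, 1]")

    @property
    def icc(self) -> float:
        tot = self.group_sd_min ** 2 + self.resid_sd_min ** 2
        return self.group_sd_min ** 2 / tot if tot else 0.0


def gen_assays(params: AssaySimParams) -> list[AssayRecord]:
    """Simulate knockdown trials from the random-intercept model.

    With the altitude effect and covariate effects at zero, high and low
    bands are identical in law; with all sds at zero every time equals the
    deterministic predictor.
    """
    rng = np.random.default_rng(params.seed)
    pre39_p = {"high": params.pre39_prob_high, "low": params.pre39_prob_low}

    rows = []
    for g in range(params.n_groups):
        u_g = rng.normal(0.0, params.group_sd_min)
        for band in params.bands:
            for i in range(params.n_per_group_band):
                heating = float(np.clip(rng.normal(15.0, 3.0), 5.0, 30.0))
                wing = float(np.clip(rng.normal(400.0, 80.0), 100.0, 800.0))
                temp_ko = float(np.clip(rng.normal(40.0, 0.6), 39.0, 41.9))
                sex = "F" if rng.random() < 0.5 else "M"
                pre39 = rng.random() < pre39_p[band]
                if pre39:
                    temp_ko = float(rng.uniform(35.0, 39.0))
                rows.append((g, band, u_g, heating, wing, temp_ko, sex, pre39,
                             rng.normal(0.0, params.resid_sd_min)))

    eta = np.array([
        params.baseline_min
        + params.altitude_effect_min * (band == "low")
        + params.beta_heating_min_per_min * (heating - 15.0)
        + params.beta_temp_ko_min_per_c * (temp_ko - 40.0)
        + params.beta_wing_min_per_mm2 * (wing - 400.0)
        for (g, band, u, heating, wing, temp_ko, sex, pre39, eps) in rows])
    eta_bar = float(np.mean(eta))
    if eta_bar <= 0:
        raise ValueError("mean deterministic predictor must be positive")
    # lognormal mean correction: E[T] equals the deterministic predictor
    sigma_z2 = (params.group_sd_min ** 2 + params.resid_sd_min ** 2) / eta_bar ** 2

    records = []
    for k, (g, band, u, heating, wing, temp_ko, sex, pre39, eps) in enumerate(rows):
        z = (u + eps) / eta_bar - 0.5 * sigma_z2
        t = eta[k] * math.exp(z)
        censored = t >= params.censor_horizon_min
        t = params.censor_horizon_min if censored else max(t, 0.1)
        records.append(AssayRecord(
            individual_id=f"ind{k:04d}",
            group=f"{params.group_kind[:2]}{g + 1:02d}",
            group_kind=params.group_kind,
            altitude_band=band, sex=sex, wing_area_mm2=wing,
            heating_up_min=heating, knockdown_min=float(t),
            censored=bool(censored), temp_at_ko_c=float(temp_ko),
            development_days=(float(np.clip(rng.normal(24.0, 2.0), 15, 40))
                              if params.group_kind == "brood" else None),
            egg_number=(float(rng.integers(5, 60))
                        if params.group_kind == "brood" else None),
        ))
    return records


def wild_survey_params(seed: int = 12345, **overrides) -> AssaySimParams:
    """Wild-survey preset (species grouping)."""
    return replace(AssaySimParams(seed=seed), **overrides)


def common_garden_params(seed: int = 12345, **overrides) -> AssaySimParams:
    """Common-garden preset: 15 broods of one widespread species, the
    altitude contrast largely gone (plasticity), brood ICC ≈ 0.25."""
    base = AssaySimParams(
        n_groups=15, n_per_group_band=9, group_kind="brood",
        baseline_min=11.0, altitude_effect_min=1.4,
        group_sd_min=2.9, resid_sd_min=5.0,
        pre39_prob_high=0.10, pre39_prob_low=0.08, seed=seed)
    return replace(base, **overrides)
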
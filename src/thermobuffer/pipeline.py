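"""End-to-end pipeline: simulate → summarize → vpd → bioclim → compare →
tolerance, with a hash manifest.

Stages communicate only through CSV files under the configured output
directory, so each stage is independently re-runnable.  With a fixed seed
and unchanged config, every output file is byte-identical across runs (the
manifest's timestamp is the single run-specific field).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from datetime import datetime, timezone

import pandas as pd

from . import bioclim as bc
from . import io as tio
from . import microclimate as mc
from . import tolerance as tol
from .vpd import vpd_series, vpd_summaries
from .simulate import (
    AssaySimParams,
    MicroclimateSimParams,
    gen_assays,
    gen_interpolated_table,
    gen_microclimate,
    wild_survey_params,
)
from .types import RunConfig

log = logging.getLogger("thermobuffer")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Any stage failure raises, after writing the partial manifest.  Inputs
    may come from the simulate stage or from the configured CSV paths; a
    stage whose inputs are absent is a hard error naming the stage.
    """
    out = config.outdir
    datadir = os.path.join(out, "data")
    os.makedirs(datadir, exist_ok=True)
    manifest: dict = {"stages": [], "files": {}, "seed": config.seed,
                      "config": config.to_dict()}

    def record(stage: str, paths: list[str]) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["files"][os.path.relpath(p, out)] = _sha256(p)

    try:
        _run_stages(config, datadir, out, record)
    finally:
        manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
        with open(os.path.join(out, "pipeline_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_stages(config: RunConfig, datadir: str, out: str, record) -> None:
    enabled = set(config.stages)

    meta_csv = config.meta_csv
    interp_csv = config.interp_csv
    assays_csv = config.assays_csv
    logger_dir = None

    if "simulate" in enabled:
        mparams = MicroclimateSimParams(
            sites_per_area=config.sim_sites_per_area,
            humidity_sites_per_area=config.sim_humidity_sites,
            n_days=config.sim_n_days, seed=config.seed)
        metas, series = gen_microclimate(mparams)
        logger_dir = os.path.join(datadir, "loggers")
        os.makedirs(logger_dir, exist_ok=True)
        paths = []
        for lid, ser in series.items():
            p = os.path.join(logger_dir, f"{lid}.csv")
            tio.write_logger_csv(ser, p)
            paths.append(p)
        meta_csv = os.path.join(datadir, "logger_meta.csv")
        pd.DataFrame([dataclasses.asdict(m) for m in metas.values()]) \
            .to_csv(meta_csv, index=False, float_format="%.4f")
        paths.append(meta_csv)

        bias = {a: {"t_max": config.sim_interp_bias_tmax_high_c, "t_min": 0.0}
                for a in mparams.areas if a.endswith("high")}
        interp_csv = os.path.join(datadir, "interpolated_climate.csv")
        gen_interpolated_table(series, metas, bias=bias,
                               min_hours=config.min_hours) \
            .to_csv(interp_csv, index=False, float_format="%.4f")
        paths.append(interp_csv)

        aparams = wild_survey_params(
            seed=config.seed, n_groups=config.sim_n_groups,
            n_per_group_band=config.sim_n_per_group_band)
        assays_csv = os.path.join(datadir, "assays.csv")
        tio.write_assay_csv(gen_assays(aparams), assays_csv)
        paths.append(assays_csv)
        record("simulate", paths)

    # --- load logger data -------------------------------------------------
    need_loggers = enabled & {"summarize", "vpd", "bioclim", "compare"}
    metas = series = None
    if need_loggers:
        if meta_csv is None:
            raise RuntimeError("stage 'summarize': no logger metadata "
                               "(enable simulate or set meta_csv)")
        metas = tio.read_meta_csv(meta_csv)
        src = logger_dir or config.loggers_csv
        if src is None:
            raise RuntimeError("stage 'summarize': no logger CSV directory")
        series = {lid: tio.read_logger_csv(os.path.join(src, f"{lid}.csv"), m)
                  for lid, m in metas.items()}

    dailies = None
    if "summarize" in enabled:
        dailies = {lid: mc.daily_summaries(s, min_hours=config.min_hours)
                   for lid, s in series.items()}
        annual = mc.annual_summaries(dailies, thresholds=config.temp_thresholds)
        offsets = mc.stratum_offsets(dailies, metas)
        slopes = mc.buffering_slopes_by_area(series, metas)
        lapse = pd.DataFrame([mc.lapse_rate(annual, metas)])
        daily_all = pd.concat(dailies.values(), ignore_index=True)
        daily_all = daily_all.assign(date=daily_all["date"].dt.strftime("%Y-%m-%d"))
        paths = tio.write_report(
            {"daily_summary": daily_all, "annual_summary": annual,
             "offsets": offsets, "slopes": slopes, "lapse_rate": lapse},
            os.path.join(out, "summarize"), config)
        record("summarize", paths)

    if "vpd" in enabled:
        rows, hourly_frames = [], []
        for lid, s in series.items():
            if not s.meta.has_humidity:
                continue
            hv = vpd_series(s)
            summ = vpd_summaries(hv, thresholds=(config.vpd_threshold_hpa,),
                                 min_hours=config.min_hours)
            rows.append({"logger_id": lid, "area": s.meta.area,
                         "stratum": s.meta.stratum, **summ})
            hourly_frames.append(hv.assign(logger_id=lid))
        if rows:
            hourly = pd.concat(hourly_frames, ignore_index=True)
            hourly = hourly.assign(
                timestamp=hourly["timestamp"].dt.strftime("%Y-%m-%d %H:%M"))
            paths = tio.write_report(
                {"vpd_summary": pd.DataFrame(rows), "vpd_hourly": hourly},
                os.path.join(out, "vpd"), config)
            record("vpd", paths)
        else:
            log.warning("vpd stage enabled but no humidity loggers; skipped")

    monthly = None
    if enabled & {"bioclim", "compare"}:
        if dailies is None:
            raise RuntimeError("stage 'bioclim': requires the summarize stage")
        monthly = {lid: bc.monthly_stats(d) for lid, d in dailies.items()}

    if "bioclim" in enabled:
        rows = []
        for lid, m in monthly.items():
            seas = mc.seasonality(
                dailies[lid][dailies[lid]["complete"]]
                .groupby(dailies[lid]["date"].dt.month)["t_mean"].mean()
                .to_numpy())
            rows.append({"logger_id": lid, "area": metas[lid].area,
                         "stratum": metas[lid].stratum,
                         "bio1": bc.bio1(m), "bio2": bc.bio2(m),
                         "seasonality": seas})
        paths = tio.write_report({"bioclim": pd.DataFrame(rows)},
                                 os.path.join(out, "bioclim"), config)
        record("bioclim", paths)

    if "compare" in enabled:
        if interp_csv is None:
            raise RuntimeError("stage 'compare': no interpolated-climate table")
        interp = bc.read_interpolated_csv(interp_csv)
        offsets = bc.compare_to_interpolated(monthly, metas, interp)
        paths = tio.write_report({"offsets_vs_interp": offsets},
                                 os.path.join(out, "compare"), config)
        record("compare", paths)

    if "tolerance" in enabled:
        if assays_csv is None:
            raise RuntimeError("stage 'tolerance': no assay table")
        records = tio.read_assay_csv(assays_csv, group_kind="species")
        retained, qc = tol.qc_filter(records,
                                     overheat_limit_c=config.overheat_limit_c,
                                     min_group_n=config.min_group_n)
        pre39 = tol.pre39_by_band(retained)
        curves = tol.curves_to_frame(tol.resistance_curves(retained))
        high = [r for r in retained if r.altitude_band == "high"]
        low = [r for r in retained if r.altitude_band == "low"]
        chi2, p = tol.logrank_test(high, low)
        anova = tol.group_anova(retained)
        rpt = tol.repeatability(retained, n_boot=config.n_boot,
                                seed=config.seed)
        sel = tol.backward_select(retained, terms=list(tol.WILD_TERMS))
        fit = tol.fit_lmm(retained, terms=list(tol.WILD_TERMS))
        r2m, r2c = fit.r2_nakagawa()
        lmm_tbl = pd.DataFrame({"term": fit.fe_names, "coef": fit.fe_params,
                                "se": fit.fe_se})
        summary = pd.DataFrame([{
            **qc.to_dict(), "logrank_chi2": chi2, "logrank_p": p,
            "anova_F": anova["F"], "anova_df1": anova["df_between"],
            "anova_df2": anova["df_within"], "anova_p": anova["p"],
            "repeatability": rpt.repeatability, "repeat_ci_low": rpt.ci_low,
            "repeat_ci_high": rpt.ci_high, "repeat_p": rpt.p_lrt,
            "r2_marginal": r2m, "r2_conditional": r2c,
        }])
        paths = tio.write_report(
            {"qc_report": pd.DataFrame([qc.to_dict()]),
             "pre39_proportions": pre39, "curves": curves,
             "lmm_fit": lmm_tbl, "selection_trace": sel.trace_frame(),
             "tolerance_summary": summary},
            os.path.join(out, "tolerance"), config)
        record("tolerance", paths)
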
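"""Heat-knockdown assay analysis.

Covers the full assay workflow: quality filtering, pre-39 °C knockdown
proportions, product-limit resistance curves with log-rank comparison,
random-intercept mixed models of knockdown time, repeatability (intra-class
correlation) with a parametric bootstrap, likelihood-ratio backward
selection, and Nakagawa–Schielzeth R².

Censoring convention: individuals still standing at the 60-min horizon enter
the mixed models and ANOVA as observed values of 60 (the convention of the
assay protocol), but are treated as right-censored by the survival-curve and
log-rank machinery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .lmm import (
    LMMResults,
    RandomInterceptLMM,
    build_design,
    lr_test,
    reml_loglik_norandom,
    fit_ols_loglik,
)
from .types import AssayRecord, assays_to_frame

# --------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    n_input: int
    n_removed_overheat: int
    n_removed_below_range: int
    n_removed_rare_groups: int
    n_censored: int
    n_retained: int

    def to_dict(self) -> dict:
        return vars(self).copy()


def qc_filter(records: list[AssayRecord], overheat_limit_c: float = 41.9,
              min_group_n: int = 5) -> tuple[list[AssayRecord], QCReport]:
    """Apply the assay quality rules, in order.

    1. assays whose chamber exceeded ``overheat_limit_c`` are removed;
    2. assays where the chamber fell below the 39 °C floor are removed;
    3. (group × altitude) cells with ``min_group_n`` or fewer individuals
       are removed — strictly more than five are needed to keep a species
       at an elevation.

    60-min survivors are retained (censored, sentinel time 60).
    """
    n_input = len(records)
    keep = [r for r in records if r.temp_at_ko_c <= overheat_limit_c]
    n_over = n_input - len(keep)

    keep2 = [r for r in keep if not r.below_range]
    n_below = len(keep) - len(keep2)

    counts: dict[tuple[str, str], int] = {}
    for r in keep2:
        counts[(r.group, r.altitude_band)] = counts.get((r.group, r.altitude_band), 0) + 1
    keep3 = [r for r in keep2 if counts[(r.group, r.altitude_band)] > min_group_n]
    n_rare = len(keep2) - len(keep3)

    report = QCReport(
        n_input=n_input, n_removed_overheat=n_over,
        n_removed_below_range=n_below, n_removed_rare_groups=n_rare,
        n_censored=sum(r.censored for r in keep3), n_retained=len(keep3),
    )
    if not keep3:
        import logging
        logging.getLogger("thermobuffer").warning("QC removed every record")
    return keep3, report


# --------------------------------------------------------------------------
# proportions and curves


def pre39_proportion(records: list[AssayRecord]) -> dict:
    """Share of individuals knocked down before the chamber reached 39 °C,
    with a Wilson 95% confidence interval."""
    if not records:
        raise ValueError("empty group")
    k = sum(r.pre39_knockdown for r in records)
    n = len(records)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return {"n_pre39": int(k), "n": int(n), "proportion": k / n,
            "ci_low": float(lo), "ci_high": float(hi)}


def pre39_by_band(records: list[AssayRecord]) -> pd.DataFrame:
    rows = []
    for band in sorted({r.altitude_band for r in records}):
        d = pre39_proportion([r for r in records if r.altitude_band == band])
        rows.append({"altitude_band": band, **d})
    return pd.DataFrame(rows)


@dataclass
class ResistanceCurve:
    """Product-limit estimate of the proportion still resisting knockdown."""

    group: str
    times: np.ndarray           # event/censor times (min), ordered
    survival: np.ndarray        # P(still standing) just after each time
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def resistance_curves(records: list[AssayRecord],
                      by: str = "altitude_band") -> dict[str, ResistanceCurve]:
    """Kaplan–Meier resistance curves, one per level of ``by``
    ("altitude_band" or "group").  Censored survivors contribute risk time
    up to the 60-min horizon."""
    df = assays_to_frame(records)
    out = {}
    for label, grp in df.groupby(by):
        km = KaplanMeierFitter()
        events = ~grp["censored"].to_numpy()
        km.fit(grp["knockdown_min"], event_observed=events)
        tbl = km.survival_function_
        times = tbl.index.to_numpy(dtype=float)
        surv = tbl.iloc[:, 0].to_numpy(dtype=float)
        at_risk = km.event_table["at_risk"].reindex(tbl.index).to_numpy(dtype=float)
        out[str(label)] = ResistanceCurve(
            group=str(label), times=times, survival=surv, at_risk=at_risk,
            n=int(len(grp)), n_events=int(events.sum()))
    return out


def curves_to_frame(curves: dict[str, ResistanceCurve]) -> pd.DataFrame:
    frames = []
    for label, c in curves.items():
        frames.append(pd.DataFrame({"group": label, "time_min": c.times,
                                    "surviving": c.survival,
                                    "at_risk": c.at_risk}))
    return pd.concat(frames, ignore_index=True)


def logrank_test(records_a: list[AssayRecord],
                 records_b: list[AssayRecord]) -> tuple[float, float]:
    """Two-group log-rank test (1 df) on knockdown times: (chi2, p)."""
    ta = np.array([r.knockdown_min for r in records_a])
    tb = np.array([r.knockdown_min for r in records_b])
    ea = np.array([not r.censored for r in records_a])
    eb = np.array([not r.censored for r in records_b])
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no knockdown events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# --------------------------------------------------------------------------
# mixed models

WILD_TERMS = ["altitude_band", "sex", "wing_area_mm2",
              "altitude_band:sex", "altitude_band:wing_area_mm2",
              "sex:wing_area_mm2", "heating_up_min", "temp_at_ko_c"]
BROOD_TERMS = WILD_TERMS + ["development_days", "egg_number"]


def fit_lmm(data, terms: list[str], grouping: str = "group",
            response: str = "knockdown_min", reml: bool = True,
            standardize: bool = True) -> LMMResults:
    """REML (or ML) fit of knockdown time on standardised fixed effects with
    a random intercept per species/brood.  ``data`` may be a DataFrame or a
    list of assay records."""
    df = data if isinstance(data, pd.DataFrame) else assays_to_frame(data)
    model = RandomInterceptLMM.from_dataframe(
        df, response=response, terms=terms, grouping=grouping,
        standardize=standardize)
    return model.fit(reml=reml)


def group_anova(data, grouping: str = "group",
                response: str = "knockdown_min") -> dict:
    """One-way fixed-effects ANOVA of knockdown time across groups."""
    df = data if isinstance(data, pd.DataFrame) else assays_to_frame(data)
    samples = [g[response].to_numpy(dtype=float)
               for _, g in df.groupby(grouping)]
    k, n = len(samples), sum(len(s) for s in samples)
    if k < 2 or n <= k:
        raise ValueError("degenerate one-way design")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance: F undefined")
    f, p = stats.f_oneway(*samples)
    return {"F": float(f), "df_between": k - 1, "df_within": n - k,
            "p": float(p)}


@dataclass
class VarianceComponents:
    """Repeatability (ICC) of knockdown time with bootstrap uncertainty."""

    repeatability: float
    sigma2_group: float
    sigma2_resid: float
    se: float
    ci_low: float
    ci_high: float
    p_lrt: float
    lrt_stat: float
    n_boot: int
    n_boot_failed: int

    def to_dict(self) -> dict:
        return vars(self).copy()


def repeatability(data, grouping: str = "group",
                  response: str = "knockdown_min", n_boot: int = 1000,
                  seed: int = 1, boundary_mixture: bool = False) -> VarianceComponents:
    """Intra-class correlation from the intercept-only random-intercept model.

    R = sigma2_group / (sigma2_group + sigma2_resid).  Uncertainty comes from
    ``n_boot`` parametric-bootstrap refits (simulate from the fitted model,
    refit, percentile 2.5/97.5 interval; failures dropped and counted); the
    p-value is a likelihood-ratio test of sigma2_group = 0 (plain chi2_1 by
    default — conservative at the boundary — or the half-mixture reference
    with ``boundary_mixture=True``).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = data if isinstance(data, pd.DataFrame) else assays_to_frame(data)
    y = df[response].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    model = RandomInterceptLMM(y, X, df[grouping].to_numpy(),
                               fe_names=["Intercept"], group_name=grouping)
    fit = model.fit(reml=True)

    llf0 = reml_loglik_norandom(y, X)
    lrt_stat, p = lr_test(fit.llf, llf0, df=1, boundary=boundary_mixture)

    rng = np.random.default_rng(seed)
    boots, failed = [], 0
    for _ in range(n_boot):
        yb = fit.simulate(rng)
        try:
            m = RandomInterceptLMM(yb, X, model.group_idx)
            boots.append(m.fit(reml=True, polish=False).repeatability)
        except Exception:
            failed += 1
    boots = np.asarray(boots)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if len(boots)
              else (np.nan, np.nan))
    return VarianceComponents(
        repeatability=fit.repeatability, sigma2_group=fit.sigma2_group,
        sigma2_resid=fit.sigma2_resid,
        se=float(boots.std(ddof=1)) if len(boots) > 1 else np.nan,
        ci_low=float(np.clip(lo, 0, 1)), ci_high=float(np.clip(hi, 0, 1)),
        p_lrt=p, lrt_stat=lrt_stat, n_boot=n_boot, n_boot_failed=failed)


# --------------------------------------------------------------------------
# backward selection


@dataclass
class SelectionResult:
    final_terms: list[str]
    random_effect_retained: bool
    trace: list[dict] = field(default_factory=list)
    final_fit: object = None

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


def _droppable(terms: list[str]) -> list[str]:
    """Terms not contained in any remaining interaction (marginality)."""
    protected = set()
    for t in terms:
        if ":" in t:
            protected.update(t.split(":"))
    return [t for t in terms if t not in protected]


def backward_select(data, terms: list[str], grouping: str = "group",
                    response: str = "knockdown_min", alpha: float = 0.05,
                    standardize: bool = True) -> SelectionResult:
    """Likelihood-ratio backward selection, random effect first.

    The random intercept is tested by REML LRT against the no-random model;
    fixed-effect terms are then dropped one at a time — always the largest
    LRT p-value above ``alpha`` among terms whose main effects are not
    protected by a surviving interaction — using ML likelihoods.  The final
    model is refit by REML (or OLS if the random effect was dropped).
    """
    df = data if isinstance(data, pd.DataFrame) else assays_to_frame(data)
    trace: list[dict] = []
    terms = list(terms)

    def make_model(tms):
        return RandomInterceptLMM.from_dataframe(
            df, response=response, terms=tms, grouping=grouping,
            standardize=standardize)

    # step 1: random effect (REML likelihoods, same fixed design)
    full = make_model(terms)
    fit_re = full.fit(reml=True)
    llf0 = reml_loglik_norandom(full.y, full.X)
    stat, p = lr_test(fit_re.llf, llf0, df=1)
    keep_random = p <= alpha
    trace.append({"step": 0, "effect": f"(1|{grouping})", "kind": "random",
                  "lrt": stat, "df": 1, "p": p,
                  "action": "kept" if keep_random else "dropped"})

    def ml_llf(tms):
        if keep_random:
            return make_model(tms).fit(reml=False).llf
        X, *_ = build_design(df, tms, standardize)
        return fit_ols_loglik(df[response].to_numpy(dtype=float), X)

    # step 2: fixed effects, one at a time
    step = 1
    while True:
        llf_full = ml_llf(terms)
        cand = []
        for t in _droppable(terms):
            reduced = [x for x in terms if x != t]
            mdl = make_model(terms)
            df_t = len(mdl.term_slices[t])
            stat, p = lr_test(llf_full, ml_llf(reduced), df=df_t)
            cand.append((p, stat, df_t, t))
        if not cand:
            break
        p, stat, df_t, worst = max(cand)
        if p <= alpha:
            for p2, stat2, df2, t2 in sorted(cand, reverse=True):
                trace.append({"step": step, "effect": t2, "kind": "fixed",
                              "lrt": stat2, "df": df2, "p": p2,
                              "action": "kept"})
            break
        trace.append({"step": step, "effect": worst, "kind": "fixed",
                      "lrt": stat, "df": df_t, "p": p, "action": "dropped"})
        terms = [x for x in terms if x != worst]
        step += 1

    if keep_random:
        final_fit = make_model(terms).fit(reml=True)
    else:
        import statsmodels.api as sm
        X, names, _, _ = build_design(df, terms, standardize)
        final_fit = sm.OLS(df[response].to_numpy(dtype=float), X).fit()
    return SelectionResult(final_terms=terms,
                           random_effect_retained=keep_random,
                           trace=trace, final_fit=final_fit)


def r2_lmm(fit: LMMResults) -> tuple[float, float]:
    """(marginal, conditional) Nakagawa–Schielzeth R² of a fitted LMM."""
    return fit.r2_nakagawa()
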
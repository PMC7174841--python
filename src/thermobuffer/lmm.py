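"""Gaussian random-intercept mixed models via the profiled likelihood.

The only random structure the analyses need is a single random intercept for
one grouping factor (species or brood mother), so the model is

    y = X beta + Z u + eps,   u ~ N(0, sigma2_g I),  eps ~ N(0, sigma2_e I)

with Z the group-indicator matrix.  Writing lambda = sigma2_g / sigma2_e,
the marginal covariance is sigma2_e (I + lambda Z Z'), block diagonal with
per-group blocks I + lambda J whose inverse and determinant are closed form
(Woodbury):

    (I + lambda J)^-1 = I - lambda/(1 + lambda n_i) J
    |I + lambda J|    = 1 + lambda n_i

Profiling beta (GLS) and sigma2_e leaves a one-dimensional REML or ML
criterion in lambda, optimised by bounded scalar search with an explicit
boundary check at lambda = 0.  This makes a fit cheap enough to run the
tens of thousands of refits the parametric bootstrap and the calibration
simulations require; agreement with general-purpose REML implementations is
verified in the test suite.

Fixed-effect design matrices are built from a term list; continuous
covariates are standardised to mean 0 / unit variance by default (as is
usual before mixed-model fitting to help interpretation and convergence),
categoricals get treatment coding, and "a:b" denotes a pairwise interaction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOG2PI = math.log(2.0 * math.pi)


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s)


def build_design(data: pd.DataFrame, terms: list[str], standardize: bool = True):
    """Build (X, column_names, term_slices, scaling) for an intercept + terms
    design.

    Returns the n×p matrix including the leading intercept column, the
    per-column names, a mapping term → column indices, and the
    (mean, sd) pairs used to standardise each continuous covariate.
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    term_slices: dict[str, list[int]] = {}
    scaling: dict[str, tuple[float, float]] = {}

    def base_columns(var: str) -> tuple[list[np.ndarray], list[str]]:
        s = data[var]
        if _is_numeric(s):
            x = s.to_numpy(dtype=float)
            if standardize:
                mu, sd = float(x.mean()), float(x.std(ddof=1))
                scaling[var] = (mu, sd)
                x = (x - mu) / sd if sd > 0 else x - mu
            return [x], [var]
        levels = sorted(pd.unique(s.astype(str)))
        out_c, out_n = [], []
        for lev in levels[1:]:  # treatment coding, first level = reference
            out_c.append((s.astype(str) == lev).to_numpy(dtype=float))
            out_n.append(f"{var}[{lev}]")
        return out_c, out_n

    for term in terms:
        parts = term.split(":")
        mats, labs = base_columns(parts[0])
        for part in parts[1:]:
            m2, l2 = base_columns(part)
            mats = [a * b for a in mats for b in m2]
            labs = [f"{a}:{b}" for a in labs for b in l2]
        idx = list(range(len(names), len(names) + len(mats)))
        term_slices[term] = idx
        cols.extend(mats)
        names.extend(labs)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    return X, names, term_slices, scaling


@dataclass
class LMMResults:
    """REML/ML fit of a random-intercept model.

    ``sigma2_group`` and ``sigma2_resid`` are the variance components;
    ``sigma2_fixed`` is the variance of the fixed-effect linear predictor
    over the data (used by the Nakagawa–Schielzeth R²).
    """

    model: "RandomInterceptLMM"
    fe_params: np.ndarray
    fe_se: np.ndarray
    fe_names: list[str]
    sigma2_group: float
    sigma2_resid: float
    llf: float
    reml: bool
    converged: bool = True

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def sigma2_fixed(self) -> float:
        eta = self.model.X @ self.fe_params
        return float(np.var(eta, ddof=1)) if len(eta) > 1 else 0.0

    @property
    def repeatability(self) -> float:
        """Intra-class correlation sigma2_g / (sigma2_g + sigma2_e)."""
        tot = self.sigma2_group + self.sigma2_resid
        return self.sigma2_group / tot if tot > 0 else 0.0

    def r2_nakagawa(self) -> tuple[float, float]:
        """(marginal, conditional) R² for the Gaussian identity-link model."""
        sf, sg, se = self.sigma2_fixed, self.sigma2_group, self.sigma2_resid
        tot = sf + sg + se
        if tot <= 0:
            raise ValueError("all variance components are zero")
        return sf / tot, (sf + sg) / tot

    def predict(self) -> np.ndarray:
        """Fixed-effect (population-level) predictions."""
        return self.model.X @ self.fe_params

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (parametric bootstrap)."""
        m = self.model
        u = rng.normal(0.0, math.sqrt(max(self.sigma2_group, 0.0)), m.n_groups)
        eps = rng.normal(0.0, math.sqrt(max(self.sigma2_resid, 0.0)), m.nobs)
        return m.X @ self.fe_params + u[m.group_idx] + eps

    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.fe_params / self.fe_se

    def summary(self) -> str:
        meth = "REML" if self.reml else "ML"
        lines = [
            f"Random-intercept LMM ({meth})",
            f"  n obs: {self.nobs}   groups ({self.model.group_name}): "
            f"{self.model.n_groups}   log-likelihood: {self.llf:.3f}",
            f"  sigma2_group: {self.sigma2_group:.4f}   "
            f"sigma2_resid: {self.sigma2_resid:.4f}   "
            f"ICC: {self.repeatability:.3f}",
            "",
            f"  {'term':<28}{'coef':>10}{'se':>10}{'t':>8}",
        ]
        for name, b, s, t in zip(self.fe_names, self.fe_params, self.fe_se,
                                 self.tvalues()):
            lines.append(f"  {name:<28}{b:>10.4f}{s:>10.4f}{t:>8.2f}")
        return "\n".join(lines)


class RandomInterceptLMM:
    """Random-intercept Gaussian mixed model for one grouping factor.

    Construct directly from arrays or with :meth:`from_dataframe`, then call
    :meth:`fit` (REML by default, ML for likelihood-ratio tests on fixed
    effects).
    """

    def __init__(self, y, X, groups, fe_names=None, term_slices=None,
                 scaling=None, group_name: str = "group"):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if len(self.y) != len(self.X):
            raise ValueError("y and X lengths differ")
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_idx = codes
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        self.nobs, self.p = self.X.shape
        if self.nobs <= self.p + 2:
            raise ValueError("need n > p + 2 observations")
        if self.n_groups < 2:
            raise ValueError("need >= 2 groups")
        self.fe_names = list(fe_names) if fe_names is not None else \
            [f"x{i}" for i in range(self.p)]
        self.term_slices = term_slices or {}
        self.scaling = scaling or {}
        self.group_name = group_name
        # per-group row indices, fixed once
        order = np.argsort(self.group_idx, kind="stable")
        bounds = np.searchsorted(self.group_idx[order],
                                 np.arange(self.n_groups + 1))
        self._order, self._bounds = order, bounds
        self.group_sizes = np.diff(bounds)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       terms: list[str], grouping: str,
                       standardize: bool = True) -> "RandomInterceptLMM":
        X, names, slices, scaling = build_design(data, terms, standardize)
        return cls(data[response].to_numpy(dtype=float), X,
                   data[grouping].to_numpy(), fe_names=names,
                   term_slices=slices, scaling=scaling, group_name=grouping)

    def without_term(self, term: str) -> "RandomInterceptLMM":
        """A copy of this model with one fixed term's columns removed."""
        drop = set(self.term_slices[term])
        keep = [j for j in range(self.p) if j not in drop]
        slices = {}
        remap = {j: i for i, j in enumerate(keep)}
        for t, idx in self.term_slices.items():
            if t != term:
                slices[t] = [remap[j] for j in idx]
        return RandomInterceptLMM(
            self.y, self.X[:, keep], self.group_idx,
            fe_names=[self.fe_names[j] for j in keep], term_slices=slices,
            scaling=self.scaling, group_name=self.group_name)

    # -- likelihood -------------------------------------------------------
    def _group_sums(self, v: np.ndarray) -> np.ndarray:
        """Per-group sums of rows of v (v is 1-D or 2-D)."""
        out = np.zeros((self.n_groups,) + v.shape[1:])
        np.add.at(out, self.group_idx, v)
        return out

    def _profile(self, lam: float):
        """GLS at variance ratio lam: returns (beta, rss_v, logdet_v, XtVX)."""
        X, y = self.X, self.y
        Sx = self._group_sums(X)           # g × p
        Sy = self._group_sums(y)           # g
        w = lam / (1.0 + lam * self.group_sizes)   # g
        XtVX = X.T @ X - (Sx * w[:, None]).T @ Sx
        XtVy = X.T @ y - Sx.T @ (w * Sy)
        ytVy = y @ y - w @ (Sy * Sy)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - XtVy @ beta
        logdet_v = float(np.sum(np.log1p(lam * self.group_sizes)))
        return beta, max(rss, 1e-300), logdet_v, XtVX

    def _neg2ll(self, lam: float, reml: bool) -> float:
        n, p = self.nobs, self.p
        _, rss, logdet_v, XtVX = self._profile(lam)
        if reml:
            s2 = rss / (n - p)
            sign, logdet_x = np.linalg.slogdet(XtVX)
            return ((n - p) * (_LOG2PI + math.log(s2)) + logdet_v
                    + logdet_x + (n - p))
        s2 = rss / n
        return n * (_LOG2PI + math.log(s2)) + logdet_v + n

    def _dneg2ll(self, lam: float, reml: bool) -> float:
        """Analytic d/dlam of the profiled -2 log-likelihood."""
        n, p = self.nobs, self.p
        beta, rss, _, XtVX = self._profile(lam)
        denom = 1.0 + lam * self.group_sizes
        Sy = self._group_sums(self.y)
        Sx = self._group_sums(self.X)
        r_sums = (Sy - Sx @ beta) / denom          # per-group sums of V^-1 r
        drss = -float(np.sum(r_sums ** 2))
        dlogdet_v = float(np.sum(self.group_sizes / denom))
        dof = (n - p) if reml else n
        out = dof * drss / rss + dlogdet_v
        if reml:
            S = Sx / denom[:, None]
            out -= float(np.einsum("ij,jk,ik->", S, np.linalg.inv(XtVX), S))
        return out

    def fit(self, reml: bool = True, polish: bool = True) -> LMMResults:
        """Estimate variance components and fixed effects.

        The profiled criterion is minimised over the variance ratio by a
        bounded scalar search, then polished by root-finding on the analytic
        gradient (the criterion is too flat near its minimum for
        function-value search alone); ``sigma2_group`` may be estimated
        exactly 0 at the boundary.  ``polish=False`` skips the gradient
        refinement (the scalar search alone is accurate to ~1e-7 in the
        variance ratio, ample for bootstrap refits).
        """
        obj = lambda t: self._neg2ll(math.exp(t), reml)
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        lam = math.exp(res.x)
        if polish:
            grad = lambda l: self._dneg2ll(l, reml)
            try:
                lo, hi = lam / 1.5, lam * 1.5
                if grad(lo) < 0 < grad(hi):
                    lam = float(optimize.brentq(grad, lo, hi, xtol=1e-14,
                                                rtol=8.9e-16))
            except Exception:
                pass
        # boundary: sigma2_group = 0
        if self._neg2ll(0.0, reml) <= self._neg2ll(lam, reml) + 1e-10:
            lam = 0.0
        beta, rss, _, XtVX = self._profile(lam)
        dof = (self.nobs - self.p) if reml else self.nobs
        s2e = rss / dof
        cov = s2e * np.linalg.inv(XtVX)
        llf = -0.5 * self._neg2ll(lam, reml)
        return LMMResults(model=self, fe_params=beta,
                          fe_se=np.sqrt(np.diag(cov)),
                          fe_names=self.fe_names,
                          sigma2_group=lam * s2e, sigma2_resid=s2e,
                          llf=llf, reml=reml)


def fit_ols_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """ML log-likelihood of the fixed-effects-only Gaussian model."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = max(rss / n, 1e-300)
    return -0.5 * (n * (_LOG2PI + math.log(s2)) + n)


def reml_loglik_norandom(y: np.ndarray, X: np.ndarray) -> float:
    """REML log-likelihood of the model without the random intercept."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = max(rss / (n - p), 1e-300)
    sign, logdet_x = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * (_LOG2PI + math.log(s2)) + logdet_x + (n - p))


def lr_test(llf_full: float, llf_reduced: float, df: int = 1,
            boundary: bool = False) -> tuple[float, float]:
    """Likelihood-ratio test: (statistic, p).

    ``boundary=True`` applies the 0.5*chi2_0 + 0.5*chi2_1 mixture reference
    appropriate when the null pins a variance at zero; the default is the
    plain (conservative) chi-square.
    """
    stat = max(0.0, 2.0 * (llf_full - llf_reduced))
    p = float(stats.chi2.sf(stat, df))
    if boundary:
        p = 0.5 * p if stat > 0 else 1.0
    return stat, p
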
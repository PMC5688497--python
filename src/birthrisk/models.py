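"""Log-linear models of category percent against mCPR and method-mix.

For each risk category the response is the natural log of the observed
percent of births in that category, and three model variants are fitted
across surveys:

* ``m1`` — ordinary least squares on mCPR alone:
  ``log(p) = b0 + b1*mCPR``;
* ``m2`` — OLS additionally adjusted for method-mix:
  ``log(p) = b0 + b1*mCPR + b2*(%permanent) + b3*(%LARC)``;
* ``m3`` — the same mean structure plus a country random intercept,
  ``log(p) = x'b + u_country + e`` with ``u ~ N(0, tau2)`` and
  ``e ~ N(0, sigma2)``, fitted by REML.

The REML fit profiles the criterion down to a one-dimensional search over
the variance ratio ``lambda = tau2/sigma2``: for each ``lambda`` the GLS
coefficients and the profiled residual variance are available in closed
form from per-country sufficient statistics, so each criterion evaluation
is O(countries). Country intercepts are recovered afterwards as
empirical-Bayes BLUPs,

    b_i = n_i*tau2 / (n_i*tau2 + sigma2) * rbar_i,

the within-country mean residual ``rbar_i`` shrunk toward zero by the
reliability ratio.

Covariates are stored per unit percent; :func:`report_per10` rescales
slopes for display per 10 percentage points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .aggregate import SurveyAggregate
from .categories import DIMENSIONS, CategorySpec, default_specs
from .errors import ConvergenceError, FitError, ValidationError

COEF_NAMES = ("intercept", "mcpr", "pct_permanent", "pct_larc")

#: lambda = tau2/sigma2 search interval for the REML profile
_LAMBDA_LO = 1e-8
_LAMBDA_HI = 1e3


@dataclass
class ModelFit:
    """Fitted coefficients and variance components for one category."""

    dimension: str
    category_label: str
    model_variant: str                      # m1 | m2 | m3
    coef: dict[str, float]
    se: dict[str, float]
    p_value: dict[str, float]
    sigma2: float
    tau2: float | None = None               # m3 only
    random_effects: dict[str, float] | None = None   # m3 only
    n_surveys: int = 0
    n_countries: int = 0
    df_resid: int = 0
    reml_loglik: float | None = None         # m3 only

    @property
    def includes_method_mix(self) -> bool:
        return "pct_permanent" in self.coef

    def linear_predictor(self, mcpr_pct: float, pct_permanent: float,
                         pct_larc: float) -> float:
        eta = self.coef["intercept"] + self.coef["mcpr"] * mcpr_pct
        if self.includes_method_mix:
            eta += (self.coef["pct_permanent"] * pct_permanent
                    + self.coef["pct_larc"] * pct_larc)
        return eta


def build_design(aggregates: Iterable[SurveyAggregate], dimension: str,
                 label: str, zero_rule: str = "continuity",
                 continuity_c: float = 0.5) -> pd.DataFrame:
    """One design row per survey with a usable category percent.

    The response ``y`` is the natural log of the category percent. A
    survey observing zero births in the category takes, under the default
    ``continuity`` rule, the percent ``100 * continuity_c /
    n_births_window`` before logging (half a birth out of the window
    total); under ``zero_rule='drop'`` it is dropped. Surveys with no
    births in the window are always dropped for that dimension.
    """
    if zero_rule not in ("continuity", "drop"):
        raise ValidationError(f"unknown zero_rule {zero_rule!r}",
                              field="zero_rule")
    rows = []
    any_nonzero = False
    for agg in aggregates:
        pct = agg.category_pct.get((dimension, label))
        if pct is None or agg.n_births_window == 0:
            continue
        if pct <= 0:
            if zero_rule == "drop":
                continue
            pct = 100.0 * continuity_c / agg.n_births_window
        else:
            any_nonzero = True
        rows.append({
            "y": math.log(pct),
            "mcpr_pct": agg.mcpr_pct,
            "pct_permanent": agg.pct_permanent,
            "pct_larc": agg.pct_larc,
            "country_id": agg.country_id,
            "survey_id": agg.survey_id,
        })
    if not any_nonzero:
        raise FitError(
            f"category ({dimension}, {label}) is zero in every survey")
    return pd.DataFrame(rows)


def _design_matrix(rows: pd.DataFrame, include_method_mix: bool,
                   ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = ["intercept", "mcpr"]
    cols = [np.ones(len(rows)), rows["mcpr_pct"].to_numpy(float)]
    if include_method_mix:
        names += ["pct_permanent", "pct_larc"]
        cols += [rows["pct_permanent"].to_numpy(float),
                 rows["pct_larc"].to_numpy(float)]
    X = np.column_stack(cols)
    y = rows["y"].to_numpy(float)
    return X, y, names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that are linear combinations of earlier ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, :j + 1]) == \
                    np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise FitError(f"design is rank deficient; collinear columns: "
                       f"{', '.join(bad) or 'unknown'}")


def fit_ols(rows: pd.DataFrame, include_method_mix: bool, *,
            dimension: str = "", category_label: str = "") -> ModelFit:
    """Classical OLS fit of the log-linear mean model.

    Coefficients solve the least-squares normal equations; ``sigma2`` is
    RSS/(n-p); standard errors come from ``sigma2 * (X'X)^-1`` and
    p-values from the two-sided t distribution with n-p df.
    """
    X, y, names = _design_matrix(rows, include_method_mix)
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more than {p} surveys to fit {p} coefficients "
                       f"(got {n})")
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    return ModelFit(
        dimension=dimension, category_label=category_label,
        model_variant="m2" if include_method_mix else "m1",
        coef=dict(zip(names, beta)), se=dict(zip(names, se)),
        p_value=dict(zip(names, pvals)), sigma2=sigma2,
        n_surveys=n, n_countries=rows["country_id"].nunique(),
        df_resid=df)


class _GroupedStats:
    """Per-country sufficient statistics for the profiled REML criterion."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.group_ids, inv = np.unique(groups, return_inverse=True)
        k = len(self.group_ids)
        self.ni = np.bincount(inv, minlength=k).astype(float)
        self.sxx = X.T @ X
        self.sxy = X.T @ y
        self.syy = float(y @ y)
        # per-group column sums of X and y
        self.gx = np.zeros((k, self.p))
        self.gy = np.zeros(k)
        for j in range(self.p):
            self.gx[:, j] = np.bincount(inv, weights=X[:, j], minlength=k)
        self.gy = np.bincount(inv, weights=y, minlength=k)
        self.inv = inv
        self.X, self.y = X, y

    def gls(self, lam: float):
        """GLS pieces for V = I + lam * J within each country."""
        c = lam / (1.0 + lam * self.ni)           # per-group deflation
        A = self.sxx - (self.gx * c[:, None]).T @ self.gx
        b = self.sxy - self.gx.T @ (c * self.gy)
        yvy = self.syy - float(c @ (self.gy ** 2))
        beta = np.linalg.solve(A, b)
        rss_v = yvy - 2.0 * float(beta @ b) + float(beta @ A @ beta)
        rss_v = max(rss_v, 1e-300)
        return A, beta, rss_v

    def reml_neg2(self, lam: float) -> float:
        """-2 * profiled restricted log-likelihood, up to a constant."""
        A, _, rss_v = self.gls(lam)
        logdet_v = float(np.sum(np.log1p(lam * self.ni)))
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        df = self.n - self.p
        return df * math.log(rss_v / df) + logdet_v + logdet_a

    def reml_loglik(self, lam: float) -> float:
        """Full restricted log-likelihood at lam with profiled sigma2."""
        df = self.n - self.p
        return -0.5 * (self.reml_neg2(lam)
                       + df * (1.0 + math.log(2.0 * math.pi)))


def reml_criterion(rows: pd.DataFrame, lam: float,
                   include_method_mix: bool = True) -> float:
    """Restricted log-likelihood of the random-intercept model at a given
    variance ratio ``lam = tau2/sigma2`` (residual variance profiled out).

    Exposed so the maximised criterion of :func:`fit_hierarchical` can be
    compared against a grid.
    """
    X, y, names = _design_matrix(rows, include_method_mix)
    gs = _GroupedStats(X, y, rows["country_id"].to_numpy())
    return gs.reml_loglik(lam)


def blup_random_effects(beta: Mapping[str, float], tau2: float, sigma2: float,
                        rows: pd.DataFrame,
                        include_method_mix: bool = True,
                        ) -> dict[str, float]:
    """Empirical-Bayes country intercepts from a fitted mean model.

    ``b_i = n_i*tau2/(n_i*tau2 + sigma2) * rbar_i`` with ``rbar_i`` the
    mean fixed-effect residual of country i. Countries absent from
    ``rows`` are absent from the map.
    """
    X, y, names = _design_matrix(rows, include_method_mix)
    bvec = np.array([beta[nm] for nm in names])
    resid = y - X @ bvec
    groups = rows["country_id"].to_numpy()
    out: dict[str, float] = {}
    for g in pd.unique(groups):
        r = resid[groups == g]
        ni = len(r)
        shrink = (ni * tau2) / (ni * tau2 + sigma2) if \
            (ni * tau2 + sigma2) > 0 else 0.0
        out[str(g)] = float(shrink * r.mean())
    return out


def fit_hierarchical(rows: pd.DataFrame, include_method_mix: bool = True, *,
                     dimension: str = "", category_label: str = "",
                     ) -> ModelFit:
    """REML fit of the country-random-intercept log-linear model.

    The restricted likelihood is maximised over ``log(lambda)`` with a
    bounded scalar search; an exact boundary candidate ``lambda = 0`` is
    also evaluated so that data without country-level variation land on
    ``tau2 = 0`` (where the coefficients coincide with OLS). Wald standard
    errors come from the GLS covariance ``sigma2 * (X'V^-1 X)^-1``;
    p-values use a t reference with ``n - p - (countries - 1)`` df
    (floored at 1).
    """
    X, y, names = _design_matrix(rows, include_method_mix)
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more than {p} surveys (got {n})")
    _check_rank(X, names)
    groups = rows["country_id"].to_numpy()
    gs = _GroupedStats(X, y, groups)
    k = len(gs.group_ids)
    identifiable = k >= 2 and (gs.ni >= 2).any()
    if not identifiable:
        warnings.warn("country variance unidentifiable (need >=2 countries "
                      "and a country with >=2 surveys); fixing tau2 = 0",
                      stacklevel=2)
        lam_hat = 0.0
    else:
        trace: list[tuple[float, float]] = []

        def obj(loglam: float) -> float:
            val = gs.reml_neg2(math.exp(loglam))
            trace.append((math.exp(loglam), val))
            return val

        res = optimize.minimize_scalar(
            obj, bounds=(math.log(_LAMBDA_LO), math.log(_LAMBDA_HI)),
            method="bounded", options={"xatol": 1e-10})
        if not res.success:
            raise ConvergenceError(
                f"REML search did not converge: {res.message}",
                last_lambda=math.exp(res.x), trace=trace)
        lam_hat = math.exp(res.x)
        # prefer the exact boundary when it is at least as good
        if gs.reml_neg2(0.0) <= res.fun + 1e-12:
            lam_hat = 0.0

    A, beta, rss_v = gs.gls(lam_hat)
    df_profile = n - p
    sigma2 = rss_v / df_profile
    tau2 = lam_hat * sigma2
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    df_wald = max(n - p - (k - 1), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_wald)
    coef = dict(zip(names, beta))
    re = blup_random_effects(coef, tau2, sigma2, rows, include_method_mix)
    return ModelFit(
        dimension=dimension, category_label=category_label,
        model_variant="m3", coef=coef, se=dict(zip(names, se)),
        p_value=dict(zip(names, pvals)), sigma2=sigma2, tau2=tau2,
        random_effects=re, n_surveys=n, n_countries=k, df_resid=df_wald,
        reml_loglik=gs.reml_loglik(lam_hat))


def fit_category(aggregates: Sequence[SurveyAggregate], dimension: str,
                 label: str, variant: str,
                 zero_rule: str = "continuity") -> ModelFit:
    """Build the design for one category and fit one model variant."""
    rows = build_design(aggregates, dimension, label, zero_rule)
    if variant == "m1":
        return fit_ols(rows, False, dimension=dimension,
                       category_label=label)
    if variant == "m2":
        return fit_ols(rows, True, dimension=dimension, category_label=label)
    if variant == "m3":
        return fit_hierarchical(rows, True, dimension=dimension,
                                category_label=label)
    raise ValidationError(f"unknown model variant {variant!r}",
                          field="model_variant")


def fit_all_categories(aggregates: Sequence[SurveyAggregate],
                       variants: Sequence[str] = ("m1", "m2", "m3"),
                       specs: Mapping[str, CategorySpec] | None = None,
                       zero_rule: str = "continuity") -> list[ModelFit]:
    """Fit every (dimension, category, variant) combination independently."""
    specs = specs or default_specs()
    fits = []
    for dim in DIMENSIONS:
        for lab in specs[dim].labels:
            for variant in variants:
                fits.append(fit_category(aggregates, dim, lab, variant,
                                         zero_rule))
    return fits


def report_per10(fit: ModelFit) -> pd.DataFrame:
    """Display table with slopes scaled per 10 percentage points.

    Internal storage stays per unit percent; the intercept is left
    unscaled. t statistics and p-values are invariant to the rescaling.
    """
    rows = []
    for name in fit.coef:
        scale = 1.0 if name == "intercept" else 10.0
        rows.append({
            "coefficient": name,
            "estimate_per10": fit.coef[name] * scale,
            "se_per10": fit.se[name] * scale,
            "p_value": fit.p_value[name],
        })
    return pd.DataFrame(rows)
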
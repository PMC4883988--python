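"""Regression estimators and diagnostics for the administration-cost algorithm.

The cost regression links log annual administration cost to formulation and
dosing regressors::

    ln ADMINCOST = a + b0*SUBCUTANEOUS + b1*INTRAMUSCULAR + b2*DOSFREQ
                   + b3*PRODUCTBUND + b4*INDICATN + b5*DOSFREQ^2
                   + b6*DOSFREQ*INDICATN + e

Intravenous delivery is the omitted reference category. Four nested models
are fitted: A = {routes, DOSFREQ}; B = A + {PRODUCTBUND, INDICATN};
C = B + {DOSFREQ^2, DOSFREQ*INDICATN} (full unrestricted); D = C minus the
route dummies.

Estimators: ordinary least squares on the log scale (``fit_log_ols``),
generalized linear models with selectable link and variance family
(``fit_glm``), and a power-GLM / extended-estimating-equations estimator
(``fit_pglm_eee``) that estimates a Box-Cox link parameter jointly with a
power or quadratic variance function. Diagnostics cover the modified Park
test for variance-family selection, Pregibon's link test, a modified
Hosmer-Lemeshow test, Breusch-Pagan and standard-Park heteroskedasticity
checks, residual moments, and DFFITS influence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import OLSInfluence

from .cost_framework import Product, Route, Indication

__all__ = [
    "MODEL_COLUMNS",
    "FitResult",
    "TestResult",
    "ModifiedParkResult",
    "ParkAuxiliaryResult",
    "ResidualShape",
    "DfitsResult",
    "EEEResult",
    "EstimationError",
    "build_design",
    "fit_log_ols",
    "fit_glm",
    "overall_f_test",
    "nested_f_ratio",
    "nested_f_ratio_from_ssr",
    "modified_park_test",
    "fit_pglm_eee",
    "pregibon_link_test",
    "modified_hosmer_lemeshow",
    "heteroskedasticity_tests",
    "residual_shape",
    "dfits",
]


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a valid fit."""


#: regressor columns (beyond the intercept) for each nested model
MODEL_COLUMNS = {
    "A": ["subcutaneous", "intramuscular", "dosfreq"],
    "B": ["subcutaneous", "intramuscular", "dosfreq", "productbund", "indicatn"],
    "C": [
        "subcutaneous",
        "intramuscular",
        "dosfreq",
        "productbund",
        "indicatn",
        "dosfreq_sq",
        "dosfreq_x_indicatn",
    ],
    "D": ["dosfreq", "productbund", "indicatn", "dosfreq_sq", "dosfreq_x_indicatn"],
}


def build_design(products: Sequence[Product], model_id: str = "C") -> pd.DataFrame:
    """Design matrix (with ``const`` column) for one of the nested models.

    The quadratic and interaction columns are always derived from ``dosfreq``
    and ``indicatn``; they can never be set independently.
    """
    if model_id not in MODEL_COLUMNS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of A, B, C, D")
    if len(products) == 0:
        raise ValueError("products must be non-empty")
    rows = []
    for p in products:
        if p.dosfreq is None:
            raise ValueError(f"product {p.name!r} has no dosing frequency")
        sc = 1.0 if p.route == Route.SC else 0.0
        im = 1.0 if p.route == Route.IM else 0.0
        if sc + im > 1:
            raise ValueError(f"product {p.name!r} flagged both SC and IM")
        ind = 1.0 if p.indication == Indication.CHRONIC else 0.0
        rows.append(
            {
                "const": 1.0,
                "subcutaneous": sc,
                "intramuscular": im,
                "dosfreq": float(p.dosfreq),
                "productbund": 1.0 if p.bundled else 0.0,
                "indicatn": ind,
                "dosfreq_sq": float(p.dosfreq) ** 2,
                "dosfreq_x_indicatn": float(p.dosfreq) * ind,
            }
        )
    df = pd.DataFrame(rows, index=[p.name for p in products])
    return df[["const"] + MODEL_COLUMNS[model_id]]


@dataclass
class FitResult:
    """One fitted cost regression.

    ``fitted_log`` is the linear predictor; ``fitted_raw`` its inverse-link
    transform (for log-scale models, ``exp`` without any smearing factor).
    ``sigma2_pred`` is the squared log-scale prediction SE, SSR/(n-k).
    """

    estimator: str
    model_id: str
    names: list[str]
    coefficients: np.ndarray
    se_default: np.ndarray
    se_robust: np.ndarray
    residuals_log: np.ndarray
    residuals_raw: np.ndarray
    fitted_log: np.ndarray
    fitted_raw: np.ndarray
    response: np.ndarray
    design: pd.DataFrame
    r2: float
    adj_r2: float
    ssr: float
    sigma2_pred: float
    f_stat: float
    loglik: float
    aic: float
    n: int
    link: Optional[str] = None
    family: Optional[str] = None
    response_scale: str = "log"

    @property
    def k(self) -> int:
        return len(self.coefficients)

    def params(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.coefficients)))


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome at a stated significance level."""

    statistic: float
    df: tuple
    p_value: float
    decision: str  # "reject" / "fail_to_reject"
    alpha: float = 0.05
    critical_value: Optional[float] = None


def _decision(p_value: float, alpha: float) -> str:
    return "reject" if p_value < alpha else "fail_to_reject"


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the columns involved via QR pivoting
        _, r, piv = scipy.linalg.qr(mat, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag[0]]
        raise EstimationError(
            f"design matrix is rank deficient (rank {rank} < {mat.shape[1]}); "
            f"collinear columns include {bad or list(X.columns)}"
        )


def fit_log_ols(design: pd.DataFrame, response: Sequence[float]) -> FitResult:
    """OLS on the log scale. ``response`` is ln(annual cost).

    Classical (default) and HC1 heteroskedasticity-robust standard errors
    are both computed.
    """
    y = np.asarray(response, dtype=float)
    X = design
    if len(y) <= X.shape[1]:
        raise EstimationError(
            f"need more observations ({len(y)}) than parameters ({X.shape[1]})"
        )
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    res_rob = res.get_robustcov_results(cov_type="HC1")
    fitted = np.asarray(res.fittedvalues)
    resid = y - fitted
    n, k = len(y), X.shape[1]
    ssr = float(resid @ resid)
    return FitResult(
        estimator="log_ols",
        model_id="",
        names=list(X.columns),
        coefficients=np.asarray(res.params),
        se_default=np.asarray(res.bse),
        se_robust=np.asarray(res_rob.bse),
        residuals_log=resid,
        residuals_raw=np.exp(y) - np.exp(fitted),
        fitted_log=fitted,
        fitted_raw=np.exp(fitted),
        response=y,
        design=X,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        ssr=ssr,
        sigma2_pred=ssr / (n - k),
        f_stat=float(res.fvalue),
        loglik=float(res.llf),
        aic=float(res.aic),
        n=n,
        response_scale="log",
    )


_GLM_FAMILIES = {
    "gaussian": sm.families.Gaussian,
    "poisson": sm.families.Poisson,
    "gamma": sm.families.Gamma,
    "inverse_gaussian": sm.families.InverseGaussian,
}
_GLM_LINKS = {
    "identity": sm.families.links.Identity,
    "log": sm.families.links.Log,
    "power": sm.families.links.Power,
}


def fit_glm(
    design: pd.DataFrame,
    response: Sequence[float],
    link: str = "log",
    family: str = "gamma",
    power: float = 1.0,
    response_scale: str = "raw",
) -> FitResult:
    """GLM with independently chosen link function and variance family.

    The link sets the scale of estimation; the family sets the raw-scale
    variance-to-mean relationship (Gaussian: constant; Poisson: var ~ mean;
    gamma: var ~ mean^2; inverse Gaussian: var ~ mean^3). Non-convergence
    raises :class:`EstimationError`; no partial result is returned.
    """
    y = np.asarray(response, dtype=float)
    if family in ("gamma", "inverse_gaussian") and np.any(y <= 0):
        raise EstimationError(f"{family} family requires a strictly positive response")
    if link not in _GLM_LINKS:
        raise ValueError(f"unknown link {link!r}")
    if family not in _GLM_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    _check_rank(design)
    link_obj = _GLM_LINKS[link](power) if link == "power" else _GLM_LINKS[link]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-canonical links, non-integer poisson
        fam = _GLM_FAMILIES[family](link=link_obj)
        model = sm.GLM(y, design, family=fam)
        try:
            res = model.fit(maxiter=100, tol=1e-8)
            res_rob = model.fit(maxiter=100, tol=1e-8, cov_type="HC1")
        except Exception as exc:  # perfect separation, domain errors, ...
            raise EstimationError(f"GLM fit failed: {exc}") from exc
    if not getattr(res, "converged", True):
        raise EstimationError("GLM did not converge within 100 iterations")
    mu = np.asarray(res.fittedvalues)
    eta = np.asarray(res.predict(which="linear"))
    n, k = len(y), design.shape[1]
    resid_raw = y - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        resid_log = np.where((y > 0) & (mu > 0), np.log(y) - np.log(mu), np.nan)
    ssr = float(resid_raw @ resid_raw)
    ybar = y.mean()
    sst = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if sst > 0 else float("nan")
    return FitResult(
        estimator="glm",
        model_id="",
        names=list(design.columns),
        coefficients=np.asarray(res.params),
        se_default=np.asarray(res.bse),
        se_robust=np.asarray(res_rob.bse),
        residuals_log=resid_log,
        residuals_raw=resid_raw,
        fitted_log=eta,
        fitted_raw=mu,
        response=y,
        design=design,
        r2=r2,
        adj_r2=adj_r2,
        ssr=ssr,
        sigma2_pred=ssr / (n - k),
        f_stat=float("nan"),
        loglik=float(res.llf),
        aic=float(res.aic),
        n=n,
        link=link,
        family=family,
        response_scale=response_scale,
    )


def overall_f_test(fit: FitResult, alpha: float = 0.05) -> TestResult:
    """F-test for overall significance: F = (R^2/(k-1)) / ((1-R^2)/(n-k))."""
    n, k = fit.n, fit.k
    r2 = fit.r2
    if r2 >= 1.0:
        stat = float("inf")
    else:
        stat = (r2 / (k - 1)) / ((1.0 - r2) / (n - k))
    crit = float(scipy.stats.f.ppf(1 - alpha, k - 1, n - k))
    p = float(scipy.stats.f.sf(stat, k - 1, n - k))
    return TestResult(
        statistic=float(stat),
        df=(k - 1, n - k),
        p_value=p,
        decision=_decision(p, alpha),
        alpha=alpha,
        critical_value=crit,
    )


def nested_f_ratio_from_ssr(
    ssr_restricted: float,
    k_restricted: int,
    ssr_full: float,
    k_full: int,
    n: int,
    alpha: float = 0.05,
) -> TestResult:
    """F-ratio comparing a restricted model against the full model from SSRs.

    F = ((SSR_r - SSR_f)/q) / (SSR_f/(n - k_f)), q = k_f - k_r.
    """
    q = k_full - k_restricted
    if q <= 0:
        raise ValueError("full model must have more parameters than the restricted one")
    stat = ((ssr_restricted - ssr_full) / q) / (ssr_full / (n - k_full))
    df = (q, n - k_full)
    p = float(scipy.stats.f.sf(stat, *df))
    crit = float(scipy.stats.f.ppf(1 - alpha, *df))
    return TestResult(
        statistic=float(stat),
        df=df,
        p_value=p,
        decision=_decision(p, alpha),
        alpha=alpha,
        critical_value=crit,
    )


def nested_f_ratio(
    restricted: FitResult, full: FitResult, alpha: float = 0.05
) -> TestResult:
    """F-ratio for a nested model pair fitted to the same response."""
    if not set(restricted.names) < set(full.names):
        raise ValueError("models are not nested: restricted regressors must be a "
                         "proper subset of the full model's")
    if restricted.n != full.n:
        raise ValueError("models were fitted to different samples")
    return nested_f_ratio_from_ssr(
        restricted.ssr, restricted.k, full.ssr, full.k, full.n, alpha=alpha
    )


@dataclass(frozen=True)
class ModifiedParkResult:
    """Modified Park test: estimated over-dispersion exponent delta in
    var(y) ~ mean^delta, with Wald tests against the GLM family values
    0 (Gaussian), 1 (Poisson), 2 (gamma), 3 (inverse Gaussian)."""

    delta: float
    se: float
    ci: tuple
    family_tests: dict  # {0: TestResult, 1: ..., 2: ..., 3: ...}
    suggested_family: Optional[str]


_DELTA_FAMILY = {0: "gaussian", 1: "poisson", 2: "gamma", 3: "inverse_gaussian"}


def modified_park_test(
    fitted_raw: Sequence[float], residuals_raw: Sequence[float], alpha: float = 0.05
) -> ModifiedParkResult:
    """Gamma-family log-link GLM of squared raw residuals on ln(fitted).

    The slope approximates the over-dispersion exponent delta. Wald tests
    against delta in {0, 1, 2, 3} guide the variance-family choice; a result
    failing to reject all four (wide CI) is legal and reported as such.
    """
    mu = np.asarray(fitted_raw, dtype=float)
    r = np.asarray(residuals_raw, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("modified Park test requires strictly positive fitted values")
    r2 = r**2
    X = sm.add_constant(pd.DataFrame({"ln_fitted": np.log(mu)}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(r2, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit(
            maxiter=200, cov_type="HC1"
        )
    delta = float(res.params.iloc[1])
    se = float(res.bse.iloc[1])
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    tests = {}
    rejected = []
    for d in (0, 1, 2, 3):
        stat = (delta - d) / se if se > 0 else np.inf
        p = 2 * float(scipy.stats.norm.sf(abs(stat)))
        tests[d] = TestResult(
            statistic=float(stat), df=(1,), p_value=p, decision=_decision(p, alpha),
            alpha=alpha,
        )
        if p < alpha:
            rejected.append(d)
    not_rejected = [d for d in (0, 1, 2, 3) if d not in rejected]
    if len(not_rejected) == 1:
        suggested = _DELTA_FAMILY[not_rejected[0]]
    elif not_rejected:
        # closest non-rejected integer to the point estimate
        suggested = _DELTA_FAMILY[min(not_rejected, key=lambda d: abs(delta - d))]
    else:
        suggested = None
    return ModifiedParkResult(
        delta=delta,
        se=se,
        ci=(delta - z * se, delta + z * se),
        family_tests=tests,
        suggested_family=suggested,
    )


def pregibon_link_test(fit: FitResult, alpha: float = 0.05) -> TestResult:
    """Pregibon's link test: refit the response on the linear predictor and
    its square; a significant squared term signals link misspecification."""
    eta = fit.fitted_log
    y = fit.response
    if np.allclose(y, fit.fitted_raw if fit.response_scale == "raw" else fit.fitted_log):
        return TestResult(0.0, (1,), 1.0, "fail_to_reject", alpha)
    X = pd.DataFrame({"const": 1.0, "eta": eta, "eta_sq": eta**2})
    if np.ptp(eta) < 1e-12:
        return TestResult(0.0, (1,), 1.0, "fail_to_reject", alpha)
    if fit.estimator == "glm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = _GLM_FAMILIES[fit.family](link=_GLM_LINKS[fit.link]())
            res = sm.GLM(y, X, family=fam).fit(maxiter=100)
        stat = float(res.params.iloc[2] / res.bse.iloc[2])
        p = 2 * float(scipy.stats.norm.sf(abs(stat)))
        df = (1,)
    else:
        res = sm.OLS(y, X).fit()
        stat = float(res.tvalues.iloc[2])
        dof = fit.n - 3
        p = 2 * float(scipy.stats.t.sf(abs(stat), dof))
        df = (dof,)
    if not np.isfinite(stat):
        stat, p = 0.0, 1.0
    return TestResult(stat, df, p, _decision(p, alpha), alpha)


def modified_hosmer_lemeshow(
    fit: FitResult, n_groups: Optional[int] = None, alpha: float = 0.05
) -> TestResult:
    """Modified Hosmer-Lemeshow test for systematic residual patterns.

    Residuals are grouped by fitted-value quantiles and an F-test checks
    that all group means are zero. Defaults to min(10, n//3) groups; small
    samples cannot support 10 groups of reasonable size.
    """
    n = fit.n
    if n_groups is None:
        n_groups = min(10, n // 3)
    if n_groups < 2 or n < 2 * n_groups:
        raise ValueError(
            f"too few observations ({n}) for {n_groups} groups; "
            "need n >= 2*n_groups — reduce n_groups"
        )
    resid = fit.residuals_raw if fit.response_scale == "raw" else fit.residuals_log
    scale = 1.0 + float(np.mean(np.abs(fit.response)))
    if np.max(np.abs(resid)) < 1e-10 * scale:  # perfect fit
        return TestResult(0.0, (n_groups, n - n_groups), 1.0, "fail_to_reject", alpha)
    order = np.argsort(fit.fitted_log, kind="stable")
    groups = np.array_split(order, n_groups)
    ss_between = sum(len(g) * np.mean(resid[g]) ** 2 for g in groups)
    ss_within = sum(float(((resid[g] - np.mean(resid[g])) ** 2).sum()) for g in groups)
    df1, df2 = n_groups, n - n_groups
    if ss_within <= 0:
        stat = 0.0 if ss_between <= 0 else float("inf")
    else:
        stat = (ss_between / df1) / (ss_within / df2)
    p = float(scipy.stats.f.sf(stat, df1, df2)) if np.isfinite(stat) else 0.0
    if stat == 0.0:
        p = 1.0
    return TestResult(float(stat), (df1, df2), p, _decision(p, alpha), alpha)


@dataclass(frozen=True)
class ParkAuxiliaryResult:
    """Standard Park auxiliary regression of exp(log-residual) on X: joint
    slope F-test plus per-regressor t-statistics and p-values."""

    joint: TestResult
    coefficients: dict
    t_values: dict
    p_values: dict


def heteroskedasticity_tests(
    fit: FitResult, alpha: float = 0.05
) -> tuple[TestResult, ParkAuxiliaryResult]:
    """Breusch-Pagan LM test plus the standard Park auxiliary regression.

    The Park regression of exp(residual) on the regressors flags which
    explanatory variables, if any, predict the log-scale error spread.
    """
    resid = fit.residuals_log
    X = fit.design
    if np.ptp(resid) < 1e-12:
        zero = TestResult(0.0, (X.shape[1] - 1,), 1.0, "fail_to_reject", alpha)
        park = ParkAuxiliaryResult(zero, {}, {}, {})
        return zero, park
    lm, lm_p, _, _ = het_breuschpagan(resid, X.to_numpy(dtype=float))
    bp = TestResult(
        float(lm), (X.shape[1] - 1,), float(lm_p), _decision(lm_p, alpha), alpha
    )
    aux = sm.OLS(np.exp(resid), X).fit()
    slope_idx = [i for i, c in enumerate(X.columns) if c != "const"]
    if slope_idx and aux.ssr > 1e-14:
        R = np.zeros((len(slope_idx), X.shape[1]))
        for row, i in enumerate(slope_idx):
            R[row, i] = 1.0
        ft = aux.f_test(R)
        joint = TestResult(
            float(ft.fvalue), (int(ft.df_num), int(ft.df_denom)), float(ft.pvalue),
            _decision(float(ft.pvalue), alpha), alpha,
        )
    else:
        joint = TestResult(0.0, (len(slope_idx), fit.n - X.shape[1]), 1.0,
                           "fail_to_reject", alpha)
    park = ParkAuxiliaryResult(
        joint=joint,
        coefficients=dict(zip(X.columns, map(float, aux.params))),
        t_values=dict(zip(X.columns, map(float, aux.tvalues))),
        p_values=dict(zip(X.columns, map(float, aux.pvalues))),
    )
    return bp, park


@dataclass(frozen=True)
class ResidualShape:
    """Residual moments: skewness and non-excess kurtosis (Gaussian = 3),
    a normality test, and the heavy-tail flag (kurtosis > 3)."""

    skewness: float
    kurtosis: float
    normality: TestResult
    leptokurtotic: bool


def residual_shape(residuals: Sequence[float], alpha: float = 0.05) -> ResidualShape:
    r = np.asarray(residuals, dtype=float)
    if len(r) < 8:
        raise ValueError("need at least 8 residuals for the normality test")
    sd = r.std(ddof=0)
    if sd == 0:
        skew, kurt = float("nan"), float("nan")
        norm = TestResult(0.0, (2,), 1.0, "fail_to_reject", alpha)
    else:
        z = (r - r.mean()) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
        stat, p = scipy.stats.normaltest(r)
        norm = TestResult(float(stat), (2,), float(p), _decision(p, alpha), alpha)
    return ResidualShape(skew, kurt, norm, bool(kurt > 3.0))


@dataclass(frozen=True)
class DfitsResult:
    """DFFITS influence values with the 2*sqrt(p/n) threshold (1.333 at
    p=8, n=18) and flags at the threshold and at twice the threshold."""

    values: np.ndarray
    threshold: float
    flagged: list
    extreme: list


def dfits(fit: FitResult) -> DfitsResult:
    """Scaled change in each fitted value on deleting that observation."""
    res = sm.OLS(fit.response, fit.design).fit()
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.asarray(OLSInfluence(res).dffits[0])
    # leverage ~ 1 makes the deletion change unbounded; flag it as infinite
    values = np.where(np.isnan(values), np.inf, values)
    p, n = fit.k, fit.n
    threshold = 2.0 * np.sqrt(p / n)
    labels = list(fit.design.index)
    flagged = [labels[i] for i in range(n) if abs(values[i]) > threshold]
    extreme = [labels[i] for i in range(n) if abs(values[i]) > 2 * threshold]
    return DfitsResult(values=values, threshold=float(threshold),
                       flagged=flagged, extreme=extreme)


# ---------------------------------------------------------------------------
# PGLM / extended estimating equations


@dataclass
class EEEResult:
    """Joint Box-Cox-link / variance-function fit.

    ``lambda_`` is the Box-Cox link parameter (0 = log link, 1 = identity-like);
    ``theta1``/``theta2`` index the variance family, quadratic
    var = theta1*mu + theta2*mu^2 or power var = theta1*mu^theta2.
    Non-convergence is reported via ``converged`` — never raised — with the
    iteration trace of estimating-equation norms.
    """

    names: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    lambda_: float
    lambda_ci: tuple
    theta1: float
    theta1_ci: tuple
    theta2: float
    theta2_ci: tuple
    converged: bool
    n_iter: int
    variance_family: str
    trace: list = field(default_factory=list)
    message: str = ""
    cov: Optional[np.ndarray] = None

    def params(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.coefficients)))


def _boxcox_mean(eta: np.ndarray, lam: float) -> np.ndarray:
    """Inverse Box-Cox link: mu = (1 + lam*eta)^(1/lam); exp(eta) at lam=0."""
    if abs(lam) < 1e-10:
        return np.exp(eta)
    u = 1.0 + lam * eta
    if np.any(u <= 0):
        return np.full_like(eta, np.nan)
    return np.exp(np.log(u) / lam)


def _dmu(eta: np.ndarray, lam: float, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(dmu/deta, dmu/dlam) for the inverse Box-Cox link."""
    if abs(lam) < 1e-6:
        dmu_deta = mu * (1.0 - lam * eta)  # first order in lam
        dlogmu_dlam = -(eta**2) / 2.0 + (2.0 / 3.0) * lam * eta**3
    else:
        u = 1.0 + lam * eta
        dmu_deta = mu / u
        dlogmu_dlam = eta / (lam * u) - np.log(u) / lam**2
    return dmu_deta, mu * dlogmu_dlam


def _variance(mu: np.ndarray, th1: float, th2: float, family: str):
    """(V, dV/dth1, dV/dth2, dV/dmu) or None when V is not positive."""
    if family == "quadratic":
        V = th1 * mu + th2 * mu**2
        dV1, dV2 = mu, mu**2
        dVmu = th1 + 2.0 * th2 * mu
    elif family == "power":
        if th1 <= 0:
            return None
        with np.errstate(over="ignore", invalid="ignore"):
            mu_p = mu**th2
        if not np.all(np.isfinite(mu_p)):
            return None
        V = th1 * mu_p
        dV1 = mu_p
        dV2 = th1 * mu_p * np.log(mu)
        dVmu = th1 * th2 * mu ** (th2 - 1.0)
    else:
        raise ValueError(f"unknown variance_family {family!r}")
    if np.any(V <= 0) or not np.all(np.isfinite(V)):
        return None
    return V, dV1, dV2, dVmu


def _eee_stack(
    p: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    variance_family: str,
    fix_lambda: Optional[float],
    fix_theta2: Optional[float],
):
    """Per-observation stacked score contributions G (n x p) and their sum U.

    Rows of the system: the quasi-score for the regression coefficients,
    and the working-normal (pseudo-likelihood) score for the link parameter
    lambda and the variance parameters. Returns None off the feasible set.
    """
    k = X.shape[1]
    beta = p[:k]
    i = k
    if fix_lambda is None:
        lam = float(p[i]); i += 1
    else:
        lam = float(fix_lambda)
    th1 = float(p[i]); i += 1
    th2 = float(fix_theta2) if fix_theta2 is not None else float(p[i])
    if abs(lam) > 5.0:
        return None
    eta = X @ beta
    mu = _boxcox_mean(eta, lam)
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        return None
    var = _variance(mu, th1, th2, variance_family)
    if var is None:
        return None
    V, dV1, dV2, dVmu = var
    r = y - mu
    dmu_deta, dmu_dlam = _dmu(eta, lam, mu)
    vres = (r**2 - V) / (2.0 * V**2)  # working-normal variance score weight
    cols = [X * (dmu_deta * r / V)[:, None]]
    if fix_lambda is None:
        cols.append((dmu_dlam * (r / V) + vres * dVmu * dmu_dlam)[:, None])
    cols.append((vres * dV1)[:, None])
    if fix_theta2 is None:
        cols.append((vres * dV2)[:, None])
    G = np.hstack(cols)
    return G.sum(axis=0), G


def _profile_beta(
    beta0: np.ndarray,
    lam: float,
    th1: float,
    th2: float,
    X: np.ndarray,
    y: np.ndarray,
    variance_family: str,
    max_iter: int = 50,
    tol: float = 1e-10,
):
    """Quasi-score IRLS for the regression coefficients at fixed (lam, theta).

    Returns (beta, converged). Damped Fisher scoring; infeasible iterates
    are rejected by step halving.
    """
    beta = beta0.copy()

    def score_info(b):
        eta = X @ b
        mu = _boxcox_mean(eta, lam)
        if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
            return None
        var = _variance(mu, th1, th2, variance_family)
        if var is None:
            return None
        V = var[0]
        dmu_deta, _ = _dmu(eta, lam, mu)
        D = X * dmu_deta[:, None]
        r = y - mu
        return D.T @ (r / V), D.T @ (D / V[:, None]), float(np.linalg.norm(r))

    cur = score_info(beta)
    if cur is None:
        return beta, False
    scale = 1.0 + float(np.linalg.norm(y))
    for _ in range(max_iter):
        score, info, _ = cur
        norm0 = float(np.linalg.norm(score))
        if norm0 < tol * scale:
            return beta, True
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        accepted = False
        for half in range(25):
            cand = beta + step * (0.5**half)
            nxt = score_info(cand)
            if nxt is None:
                continue
            if float(np.linalg.norm(nxt[0])) < norm0 or half == 24:
                beta, cur = cand, nxt
                accepted = True
                break
        if not accepted:
            return beta, False
        if np.max(np.abs(step * (0.5**half)) / (1.0 + np.abs(beta))) < 1e-12:
            break
    return beta, float(np.linalg.norm(cur[0])) < 1e-6 * scale


def fit_pglm_eee(
    design: pd.DataFrame,
    response: Sequence[float],
    variance_family: str = "quadratic",
    fix_lambda: Optional[float] = None,
    fix_theta2: Optional[float] = None,
    max_iter: int = 600,
    tol: float = 1e-6,
    alpha: float = 0.05,
) -> EEEResult:
    """Power-GLM / extended estimating equations.

    Jointly estimates the regression coefficients, the Box-Cox link
    parameter lambda, and the variance-function parameters (theta1, theta2):
    the coefficients solve the quasi-score at each candidate (lambda, theta)
    (profiled out by damped Fisher scoring), and the outer parameters
    maximise the working-normal pseudo-likelihood. The reported solution is
    a stationary point of the stacked estimating equations, and confidence
    intervals use the sandwich (robust) covariance of that system. Initial
    coefficients come from a log-link gamma GLM.

    ``fix_lambda`` / ``fix_theta2`` pin a parameter instead of estimating it
    (``fix_lambda=0`` constrains the link to log). Non-convergence is
    reported via ``converged=False`` — never raised.

    Internally the response is divided by its geometric mean so the
    optimisation is well conditioned regardless of the currency scale; the
    Box-Cox link family is closed under this scaling, so the solution is
    transformed back exactly and the covariance is evaluated on the
    original scale.
    """
    y_orig = np.asarray(response, dtype=float)
    if np.any(y_orig <= 0):
        raise ValueError("EEE requires a strictly positive response")
    if np.ptp(y_orig) < 1e-12:
        raise ValueError("response is constant: no variation to fit")
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    n, k = X.shape
    try:
        const_idx = names.index("const")
    except ValueError:
        const_idx = None
    scale = float(np.exp(np.mean(np.log(y_orig)))) if const_idx is not None else 1.0
    y = y_orig / scale

    # initial coefficients from a log-link gamma GLM on the scaled response
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        init = sm.GLM(
            y, design, family=sm.families.Gamma(link=sm.families.links.Log())
        ).fit(maxiter=200)
    beta_init = np.asarray(init.params, dtype=float)
    mu0 = np.asarray(init.fittedvalues)
    r0 = y - mu0
    if variance_family == "quadratic":
        A = np.column_stack([mu0, mu0**2])
        th, *_ = np.linalg.lstsq(A, r0**2, rcond=None)
        th1_init = float(th[0]) if th[0] > 0 else float(np.mean(r0**2 / mu0))
        th2_init = float(th[1]) if th[1] > 0 else float(np.mean(r0**2 / mu0**2))
        if fix_theta2 is not None:
            th1_init = float(np.mean(r0**2 / mu0))
    else:
        th2_init = 2.0
        th1_init = float(np.mean(r0**2 / mu0**2))

    state = {"beta": beta_init.copy(), "ok": True}

    def negloglik(outer: np.ndarray) -> float:
        i = 0
        if fix_lambda is None:
            lam = float(outer[i]); i += 1
        else:
            lam = float(fix_lambda)
        th1 = float(outer[i]); i += 1
        th2 = float(fix_theta2) if fix_theta2 is not None else float(outer[i])
        if abs(lam) > 5.0:
            return 1e10 + 1e8 * (abs(lam) - 5.0)
        beta, ok = _profile_beta(
            state["beta"], lam, th1, th2, X, y, variance_family
        )
        if not ok:
            return 1e10
        eta = X @ beta
        mu = _boxcox_mean(eta, lam)
        if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
            return 1e10
        var = _variance(mu, th1, th2, variance_family)
        if var is None:
            return 1e10
        V = var[0]
        state["beta"] = beta
        r = y - mu
        return 0.5 * float(np.sum(np.log(V) + r**2 / V))

    x0 = []
    if fix_lambda is None:
        x0.append(0.0)
    x0.append(max(th1_init, 1e-8) if variance_family == "power" else th1_init)
    if fix_theta2 is None:
        x0.append(th2_init)
    x0 = np.asarray(x0, dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = scipy.optimize.minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": max_iter,
                "maxfev": 2 * max_iter,
                "xatol": tol,
                "fatol": 1e-8,
            },
        )
    outer = np.asarray(opt.x, dtype=float)
    fval = float(opt.fun)
    message = "" if opt.success else str(opt.message)
    converged = bool(opt.success) and fval < 1e9

    # final profiled coefficients at the outer optimum
    i = 0
    if fix_lambda is None:
        lam = float(outer[i]); i += 1
    else:
        lam = float(fix_lambda)
    th1 = float(outer[i]); i += 1
    th2 = float(fix_theta2) if fix_theta2 is not None else float(outer[i])
    beta, beta_ok = _profile_beta(state["beta"], lam, th1, th2, X, y, variance_family)
    if not beta_ok:
        converged = False
        message = message or "profiled coefficient step did not converge"

    # sanity: fitted variance must live on the squared-residual scale
    eta = X @ beta
    mu = _boxcox_mean(eta, lam)
    var = _variance(mu, th1, th2, variance_family) if np.all(np.isfinite(mu)) else None
    if var is None:
        converged = False
        message = message or "solution left the feasible region"
    else:
        ratio = float(np.mean(var[0])) / max(float(np.mean((y - mu) ** 2)), 1e-300)
        if not (1e-2 < ratio < 1e2):
            converged = False
            message = message or "variance parameters drifted off the data scale"

    # back-transform to the original response scale (exact: the Box-Cox
    # link family is closed under y -> y/s)
    beta = beta.copy()
    if scale != 1.0:
        if abs(lam) < 1e-10:
            beta[const_idx] += np.log(scale)
        else:
            beta = beta * scale**lam
            beta[const_idx] += (scale**lam - 1.0) / lam
        if variance_family == "quadratic":
            th1 *= scale
        else:
            th1 *= scale ** (2.0 - th2)

    p = list(beta)
    if fix_lambda is None:
        p.append(lam)
    p.append(th1)
    if fix_theta2 is None:
        p.append(th2)
    p = np.asarray(p, dtype=float)

    # sandwich covariance of the stacked estimating equations, original scale
    def system_orig(q):
        return _eee_stack(q, X, y_orig, variance_family, fix_lambda, fix_theta2)

    cov = None
    se = np.full(len(p), np.nan)
    out = system_orig(p)
    if out is not None:
        U, G = out
        J = np.zeros((len(p), len(p)))
        feasible = True
        for j in range(len(p)):
            h = 1e-6 * max(1.0, abs(p[j]))
            qp = p.copy()
            qp[j] += h
            nxt = system_orig(qp)
            if nxt is None:
                qp[j] = p[j] - h
                nxt = system_orig(qp)
                if nxt is None:
                    feasible = False
                    break
                J[:, j] = (U - nxt[0]) / h
            else:
                J[:, j] = (nxt[0] - U) / h
        if feasible:
            B = G.T @ G * (n / max(n - len(p), 1))  # small-sample correction
            try:
                Jinv = np.linalg.inv(J)
                cov = Jinv @ B @ Jinv.T
                se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            except np.linalg.LinAlgError:
                pass

    z = float(scipy.stats.norm.ppf(1 - alpha / 2))

    def ci_at(idx):
        if cov is None or idx is None:
            return (float("nan"), float("nan"))
        return (float(p[idx] - z * se[idx]), float(p[idx] + z * se[idx]))

    i = k
    lam_idx = None
    if fix_lambda is None:
        lam_idx = i; i += 1
    th1_idx = i; i += 1
    th2_idx = i if fix_theta2 is None else None

    return EEEResult(
        names=names,
        coefficients=beta,
        se=se[:k],
        lambda_=lam,
        lambda_ci=ci_at(lam_idx),
        theta1=th1,
        theta1_ci=ci_at(th1_idx),
        theta2=th2,
        theta2_ci=ci_at(th2_idx),
        converged=converged,
        n_iter=int(opt.nit) if hasattr(opt, "nit") else 0,
        variance_family=variance_family,
        trace=[fval],
        message=message,
        cov=cov,
    )
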
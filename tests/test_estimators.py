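import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import statsmodels.api as sm

from admincost import estimators as est
from admincost.cost_framework import Product
from admincost.synthetic_data import GeneratorConfig, generate_product_sample


def _random_design(rng, n=18):
    """A model-C-shaped design with random dosing frequencies."""
    dosfreq = rng.uniform(4, 60, n)
    n_sc, n_im = max(2, n * 2 // 5), 2
    sc = np.zeros(n)
    sc[:n_sc] = 1.0
    im = np.zeros(n)
    im[n_sc:n_sc + n_im] = 1.0
    ind = np.resize([0.0, 1.0, 1.0], n)
    bund = np.resize([0.0, 1.0], n)
    return pd.DataFrame(
        {
            "const": 1.0,
            "subcutaneous": sc,
            "intramuscular": im,
            "dosfreq": dosfreq,
            "productbund": bund,
            "indicatn": ind,
            "dosfreq_sq": dosfreq**2,
            "dosfreq_x_indicatn": dosfreq * ind,
        }
    )


# ---------------------------------------------------------------------------
# design construction


def test_build_design_full_model_rows():
    iv = Product("a", "IV", "acute", False, dosfreq=17.33)
    sc = Product("b", "SC", "chronic", True, dosfreq=17.33)
    X = est.build_design([iv, sc], "C")
    np.testing.assert_allclose(
        X.loc["a"].to_numpy(), [1, 0, 0, 17.33, 0, 0, 300.3289, 0]
    )
    np.testing.assert_allclose(
        X.loc["b"].to_numpy(), [1, 1, 0, 17.33, 1, 1, 300.3289, 17.33]
    )


def test_build_design_model_a_columns():
    p = Product("a", "SC", "chronic", True, dosfreq=10.0)
    X = est.build_design([p], "A")
    assert list(X.columns) == ["const", "subcutaneous", "intramuscular", "dosfreq"]


def test_build_design_requires_dosfreq():
    p = Product("a", "IV", "chronic", False)
    with pytest.raises(ValueError, match="dosing frequency"):
        est.build_design([p], "C")


# ---------------------------------------------------------------------------
# log-OLS


def test_ols_matches_normal_equation_oracle():
    rng = np.random.default_rng(0)
    X = _random_design(rng)
    y = rng.standard_normal(18) + X["dosfreq"] * 0.1
    fit = est.fit_log_ols(X, y)
    A = X.to_numpy()
    oracle = np.linalg.solve(A.T @ A, A.T @ y)
    np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-8)
    assert fit.ssr == pytest.approx(float(np.sum(fit.residuals_log**2)))
    assert fit.adj_r2 <= fit.r2


def test_ols_exact_fit_and_intercept_only():
    rng = np.random.default_rng(1)
    X = _random_design(rng)
    beta = np.array([7.0, -3.0, -5.0, 0.4, 0.4, -0.3, -0.001, -0.3])
    y = X.to_numpy() @ beta
    fit = est.fit_log_ols(X, y)
    assert fit.r2 == pytest.approx(1.0)
    np.testing.assert_allclose(fit.residuals_log, 0.0, atol=1e-8)

    only = pd.DataFrame({"const": np.ones(10)})
    y0 = np.arange(10.0)
    fit0 = est.fit_log_ols(only, y0)
    assert fit0.coefficients[0] == pytest.approx(y0.mean())


def test_rank_deficient_design_rejected_naming_columns():
    X = pd.DataFrame({"const": np.ones(10), "a": np.arange(10.0), "b": 2 * np.arange(10.0)})
    with pytest.raises(est.EstimationError, match="rank deficient"):
        est.fit_log_ols(X, np.random.default_rng(0).standard_normal(10))


# ---------------------------------------------------------------------------
# GLM equivalences


def test_identity_gaussian_glm_equals_log_ols():
    rng = np.random.default_rng(2)
    X = _random_design(rng)
    ln_y = 7 + 0.05 * X["dosfreq"].to_numpy() + rng.standard_normal(18)
    ols = est.fit_log_ols(X, ln_y)
    glm = est.fit_glm(X, ln_y, link="identity", family="gaussian", response_scale="log")
    np.testing.assert_allclose(glm.coefficients, ols.coefficients, atol=1e-8)


def test_log_gaussian_glm_equals_nonlinear_least_squares():
    rng = np.random.default_rng(3)
    X = pd.DataFrame({"const": 1.0, "x": rng.uniform(0, 2, 60)})
    y = np.exp(1.0 + 0.8 * X["x"].to_numpy()) + rng.standard_normal(60)
    glm = est.fit_glm(X, y, link="log", family="gaussian")
    A = X.to_numpy()

    def sse(b):
        return float(np.sum((y - np.exp(A @ b)) ** 2))

    oracle = scipy.optimize.minimize(sse, [1.0, 0.8], method="Nelder-Mead",
                                     options={"xatol": 1e-10, "fatol": 1e-12}).x
    np.testing.assert_allclose(glm.coefficients, oracle, atol=1e-6)


def test_glm_log_gamma_recovers_coefficients():
    # synthetic gamma data with log-linear mean: 95% CIs cover truth >= 90%
    rng = np.random.default_rng(4)
    truth = np.array([1.0, 0.6])
    n, reps = 200, 200
    covered = np.zeros(2)
    for _ in range(reps):
        x = rng.uniform(0, 2, n)
        mu = np.exp(truth[0] + truth[1] * x)
        y = rng.gamma(shape=4.0, scale=mu / 4.0)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = est.fit_glm(X, y, link="log", family="gamma")
        lo = fit.coefficients - 1.96 * fit.se_default
        hi = fit.coefficients + 1.96 * fit.se_default
        covered += (lo <= truth) & (truth <= hi)
    assert (covered / reps >= 0.90).all()


def test_glm_requires_positive_response_for_gamma():
    X = pd.DataFrame({"const": np.ones(5)})
    with pytest.raises(est.EstimationError, match="positive"):
        est.fit_glm(X, np.array([1.0, 2.0, -1.0, 3.0, 4.0]), "log", "gamma")


# ---------------------------------------------------------------------------
# F tests


def test_overall_f_test_formula():
    rng = np.random.default_rng(5)
    X = _random_design(rng)
    y = rng.standard_normal(18)
    fit = est.fit_log_ols(X, y)
    res = est.overall_f_test(fit)
    # formula equals the ANOVA decomposition computed by statsmodels
    assert res.statistic == pytest.approx(fit.f_stat, rel=1e-6)
    k, n = fit.k, fit.n
    assert res.statistic == pytest.approx(
        (fit.r2 / (k - 1)) / ((1 - fit.r2) / (n - k)), rel=1e-12
    )


def test_overall_f_is_zero_when_r2_zero():
    rng = np.random.default_rng(20)
    X = pd.DataFrame({"const": 1.0, "x": np.arange(12.0)})
    fit = est.fit_log_ols(X, rng.standard_normal(12))
    fit.r2 = 0.0  # a regression explaining nothing
    res = est.overall_f_test(fit)
    assert res.statistic == 0.0 and res.decision == "fail_to_reject"


def test_nested_f_ratio_from_printed_ssrs():
    # restricted three-regressor model (4 params) against the full model
    a_vs_c = est.nested_f_ratio_from_ssr(17.8023, 4, 7.0858, 8, n=18)
    assert a_vs_c.statistic == pytest.approx(3.781, abs=5e-4)
    assert a_vs_c.critical_value == pytest.approx(3.478, abs=5e-3)
    b_vs_c = est.nested_f_ratio_from_ssr(16.6714, 6, 7.0858, 8, n=18)
    assert b_vs_c.statistic == pytest.approx(6.764, abs=5e-4)
    assert b_vs_c.critical_value == pytest.approx(4.1028, abs=5e-3)
    zero = est.nested_f_ratio_from_ssr(7.0858, 6, 7.0858, 8, n=18)
    assert zero.statistic == 0.0


def test_nested_f_requires_nesting(fit18, sample18):
    products = [p for p, _ in sample18]
    y = fit18.response
    model_d = est.fit_log_ols(est.build_design(products, "D"), y)
    with pytest.raises(ValueError, match="not nested"):
        est.nested_f_ratio(fit18, model_d)
    model_a = est.fit_log_ols(est.build_design(products, "A"), y)
    ratio = est.nested_f_ratio(model_a, fit18)
    assert ratio.statistic >= 0 and ratio.df == (4, 10)


# ---------------------------------------------------------------------------
# modified Park test


@pytest.mark.parametrize("delta_true", [0.0, 2.0])
def test_modified_park_recovers_overdispersion_exponent(delta_true):
    rng = np.random.default_rng(int(delta_true) + 10)
    n, reps = 200, 200
    covered = 0
    for _ in range(reps):
        mu = np.exp(rng.uniform(1.0, 4.0, n))
        sd = 0.5 * mu ** (delta_true / 2.0)
        resid = sd * rng.standard_normal(n)
        res = est.modified_park_test(mu, resid)
        lo, hi = res.ci
        covered += lo <= delta_true <= hi
    assert covered / reps >= 0.90


def test_modified_park_requires_positive_fitted():
    with pytest.raises(ValueError, match="positive"):
        est.modified_park_test([1.0, -1.0], [0.1, 0.2])


def test_modified_park_wide_ci_rejects_nothing():
    # tiny sample: failing to reject every candidate family is a legal result
    rng = np.random.default_rng(0)
    mu = np.exp(rng.uniform(1, 2, 10))
    resid = mu * rng.standard_normal(10) * 2
    res = est.modified_park_test(mu, resid)
    assert set(res.family_tests) == {0, 1, 2, 3}
    for t in res.family_tests.values():
        assert t.decision in ("reject", "fail_to_reject")


# ---------------------------------------------------------------------------
# link / residual-pattern diagnostics


def _ols_fit_from(y, X):
    return est.fit_log_ols(X, y)


def test_pregibon_link_test_null_and_power():
    rng = np.random.default_rng(6)
    n, reps = 200, 100
    null_ok = power = 0
    for _ in range(reps):
        x = rng.uniform(0, 2, n)
        X = pd.DataFrame({"const": 1.0, "x": x})
        y_null = 1.0 + 0.8 * x + 0.3 * rng.standard_normal(n)
        if est.pregibon_link_test(_ols_fit_from(y_null, X)).decision == "fail_to_reject":
            null_ok += 1
        y_quad = 1.0 + 0.8 * x + 0.8 * (1.0 + 0.8 * x) ** 2 + 0.3 * rng.standard_normal(n)
        if est.pregibon_link_test(_ols_fit_from(y_quad, X)).decision == "reject":
            power += 1
    assert null_ok / reps >= 0.90
    assert power / reps >= 0.90


def test_pregibon_perfect_fit_statistic_zero():
    X = pd.DataFrame({"const": 1.0, "x": np.arange(10.0)})
    fit = _ols_fit_from(2.0 + 3.0 * np.arange(10.0), X)
    res = est.pregibon_link_test(fit)
    assert res.statistic == 0.0 and res.decision == "fail_to_reject"


def _residual_pattern_fit(fitted, residuals):
    """Minimal FitResult carrying a fitted/residual pattern for grouping tests."""
    n = len(fitted)
    X = pd.DataFrame({"const": np.ones(n)})
    zeros = np.zeros(n)
    return est.FitResult(
        estimator="log_ols", model_id="", names=["const"],
        coefficients=np.array([0.0]), se_default=np.array([0.0]),
        se_robust=np.array([0.0]), residuals_log=np.asarray(residuals),
        residuals_raw=zeros, fitted_log=np.asarray(fitted), fitted_raw=zeros,
        response=np.asarray(fitted) + np.asarray(residuals), design=X,
        r2=0.0, adj_r2=0.0, ssr=float(np.sum(np.square(residuals))),
        sigma2_pred=1.0, f_stat=0.0, loglik=0.0, aic=0.0, n=n,
    )


def test_hosmer_lemeshow_null_and_power():
    rng = np.random.default_rng(7)
    n, reps = 200, 200
    null_ok = 0
    for _ in range(reps):
        fitted = rng.uniform(0, 10, n)
        fit = _residual_pattern_fit(fitted, rng.standard_normal(n))
        if est.modified_hosmer_lemeshow(fit).decision == "fail_to_reject":
            null_ok += 1
    assert null_ok / reps >= 0.90

    power = 0
    for _ in range(50):
        fitted = rng.uniform(0, 10, n)
        # monotone residual trend in the fitted values
        resid = 0.15 * (fitted - 5.0) + rng.standard_normal(n)
        fit = _residual_pattern_fit(fitted, resid)
        if est.modified_hosmer_lemeshow(fit).decision == "reject":
            power += 1
    assert power / 50 >= 0.80


def test_hosmer_lemeshow_edge_cases():
    X = pd.DataFrame({"const": 1.0, "x": np.arange(12.0)})
    perfect = _ols_fit_from(2.0 * np.arange(12.0), X)
    res = est.modified_hosmer_lemeshow(perfect, n_groups=3)
    assert res.statistic == 0.0 and res.decision == "fail_to_reject"
    with pytest.raises(ValueError, match="n_groups"):
        est.modified_hosmer_lemeshow(perfect, n_groups=10)


def test_heteroskedasticity_null_and_power():
    rng = np.random.default_rng(8)
    n = 200
    null_ok_bp = null_ok_park = 0
    reps = 100
    for _ in range(reps):
        x = rng.uniform(1, 5, n)
        X = pd.DataFrame({"const": 1.0, "dosfreq": x})
        fit = _ols_fit_from(1.0 + 0.2 * x + rng.standard_normal(n), X)
        bp, park = est.heteroskedasticity_tests(fit)
        null_ok_bp += bp.decision == "fail_to_reject"
        null_ok_park += park.joint.decision == "fail_to_reject"
    assert null_ok_bp / reps >= 0.90
    assert null_ok_park / reps >= 0.90

    power = 0
    for _ in range(50):
        x = rng.uniform(1, 5, n)
        X = pd.DataFrame({"const": 1.0, "dosfreq": x})
        fit = _ols_fit_from(1.0 + 0.2 * x + np.sqrt(x) * rng.standard_normal(n), X)
        bp, _ = est.heteroskedasticity_tests(fit)
        power += bp.decision == "reject"
    assert power / 50 >= 0.80


def test_heteroskedasticity_constant_residuals():
    X = pd.DataFrame({"const": 1.0, "x": np.arange(10.0)})
    fit = _ols_fit_from(5.0 + 2.0 * np.arange(10.0), X)
    bp, park = est.heteroskedasticity_tests(fit)
    assert bp.statistic == 0.0 and park.joint.statistic == 0.0


def test_residual_shape_known_distributions():
    rng = np.random.default_rng(9)
    normal = est.residual_shape(rng.standard_normal(100_000))
    assert normal.kurtosis == pytest.approx(3.0, abs=0.1)

    uniform = est.residual_shape(rng.uniform(-1, 1, 100_000))
    assert uniform.kurtosis == pytest.approx(1.8, abs=0.1)
    assert not uniform.leptokurtotic

    laplace = est.residual_shape(rng.laplace(size=100_000))
    assert laplace.kurtosis == pytest.approx(6.0, abs=0.3)
    assert laplace.leptokurtotic

    symmetric = est.residual_shape(np.concatenate([np.arange(50.0), -np.arange(50.0)]))
    assert symmetric.skewness == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# influence


def test_dfits_threshold_matches_small_sample_rule():
    rng = np.random.default_rng(10)
    X = _random_design(rng)  # p=8 columns, n=18
    fit = est.fit_log_ols(X, rng.standard_normal(18))
    res = est.dfits(fit)
    assert res.threshold == pytest.approx(2 * np.sqrt(8 / 18), abs=1e-9)
    assert res.threshold == pytest.approx(1.333, abs=1e-3)


def test_dfits_flags_constructed_outlier():
    rng = np.random.default_rng(11)
    n = 40
    X = pd.DataFrame({"const": 1.0, "x": rng.uniform(0, 1, n)})
    y = 1.0 + 2.0 * X["x"].to_numpy() + 0.1 * rng.standard_normal(n)
    y[5] += 10 * 0.1 * 10  # displace one response by ~10 sd
    fit = est.fit_log_ols(X, y)
    res = est.dfits(fit)
    assert X.index[5] in res.flagged


def test_dfits_balanced_null_flags_few_observations():
    # under a clean balanced design, influence flags are rare events
    rng = np.random.default_rng(12)
    flagged = total = 0
    for _ in range(50):
        X = pd.DataFrame({"const": 1.0, "x": np.linspace(0, 1, 30)})
        fit = est.fit_log_ols(X, 1.0 + X["x"].to_numpy() + 0.2 * rng.standard_normal(30))
        res = est.dfits(fit)
        flagged += len(res.flagged)
        total += 30
        assert len(res.extreme) <= len(res.flagged)
    assert flagged / total < 0.10


# ---------------------------------------------------------------------------
# PGLM / EEE


def test_eee_constrained_to_log_link_matches_glm_oracle():
    # lambda fixed at 0 with variance ~ mu: the quasi-score is the Poisson
    # log-link GLM score for any theta1, so coefficients must coincide
    rng = np.random.default_rng(13)
    n = 200
    x = rng.uniform(0, 2, n)
    mu = np.exp(0.5 + 0.7 * x)
    y = np.maximum(rng.poisson(mu * 3) / 3.0, 0.1)
    X = pd.DataFrame({"const": 1.0, "x": x})
    res = est.fit_pglm_eee(X, y, fix_lambda=0.0, fix_theta2=0.0)
    oracle = sm.GLM(y, X, family=sm.families.Poisson(link=sm.families.links.Log())).fit()
    assert res.converged
    np.testing.assert_allclose(res.coefficients, np.asarray(oracle.params), atol=1e-4)


def test_eee_lambda_near_zero_on_lognormal_data():
    rng = np.random.default_rng(14)
    n = 500
    x = rng.uniform(0, 2, n)
    y = np.exp(1.0 + 0.8 * x + 0.5 * rng.standard_normal(n))
    X = pd.DataFrame({"const": 1.0, "x": x})
    res = est.fit_pglm_eee(X, y)
    assert res.converged
    lo, hi = res.lambda_ci
    assert lo <= res.lambda_ <= hi
    assert abs(res.lambda_) < 1.0
    assert res.theta2 > 0  # lognormal variance is quadratic in the mean


def test_eee_rejects_degenerate_response():
    X = pd.DataFrame({"const": np.ones(10)})
    with pytest.raises(ValueError, match="variation"):
        est.fit_pglm_eee(X, np.full(10, 3.0))
    with pytest.raises(ValueError, match="positive"):
        est.fit_pglm_eee(X, np.zeros(10))


def test_eee_reports_nonconvergence_instead_of_raising():
    # a tiny, ill-posed problem: convergence failure must be a reported
    # outcome, never an exception
    rng = np.random.default_rng(15)
    pairs = generate_product_sample(GeneratorConfig(seed=3))
    products = [p for p, _ in pairs]
    X = est.build_design(products, "C")
    y = np.exp(7 + rng.standard_normal(18))
    res = est.fit_pglm_eee(X, y, variance_family="power", max_iter=40)
    assert isinstance(res.converged, bool)
    if not res.converged:
        assert res.message
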
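import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from anginatrial.ordinal import (
    CumulativeLinkFit,
    encode_ordinal,
    fit_cumulative_link,
    odds_ratio,
    rcs_basis,
    typical_patient_prediction,
    wald_p_value,
)


def proportional_odds_nll(alpha, beta, y, X):
    """Straightforward likelihood evaluation, independent of the package.

    P(Y = k) = F(alpha_k - x b) - F(alpha_{k-1} - x b), logistic F.
    """
    edges = np.concatenate([[-np.inf], alpha, [np.inf]])
    eta = X @ beta
    upper = stats.logistic.cdf(edges[y + 1] - eta)
    lower = stats.logistic.cdf(edges[y] - eta)
    return -np.sum(np.log(upper - lower))


def brute_force_fit(y, X, K):
    """Grid search plus Nelder-Mead polish of the raw likelihood."""
    def nll(params):
        alpha = params[: K - 1]
        if np.any(np.diff(alpha) <= 0):
            return 1e10
        return proportional_odds_nll(alpha, params[K - 1 :], y, X)

    grid = [slice(-3, 3.01, 0.5)] * (K - 1) + [slice(-3, 3.01, 0.5)] * X.shape[1]
    start = optimize.brute(nll, grid, finish=None)
    res = optimize.minimize(
        nll, start, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    return res.x, -res.fun


class TestOracleEquivalence:
    def test_matches_brute_force_maximum(self, oracle_dataset):
        """Quasi-Newton fit agrees with grid+simplex maximization to 1e-4."""
        y, t = oracle_dataset
        fit = fit_cumulative_link(list(y), t)
        codes = y.astype(int)
        theta, loglik = brute_force_fit(codes, t[:, None], K=3)
        assert fit.converged
        assert fit.loglik == pytest.approx(loglik, abs=1e-4)
        assert fit.beta_treatment == pytest.approx(theta[2], abs=1e-4)
        assert fit.thresholds == pytest.approx(theta[:2], abs=1e-3)

    def test_wald_interval_matches_hand_computation(self, oracle_dataset):
        y, t = oracle_dataset
        fit = fit_cumulative_link(list(y), t)
        se = fit.se_treatment
        z = stats.norm.ppf(0.975)
        or_, lo, hi = odds_ratio(fit)
        assert or_ == pytest.approx(np.exp(fit.beta_treatment))
        assert lo == pytest.approx(np.exp(fit.beta_treatment - z * se))
        assert hi == pytest.approx(np.exp(fit.beta_treatment + z * se))

    def test_ordinal_invariance_under_monotone_relabeling(self, oracle_dataset):
        """Only the ordering of outcome levels matters for the fit."""
        y, t = oracle_dataset
        fit_raw = fit_cumulative_link(list(y), t)
        transformed = [np.expm1(v) * 3 + 0.5 for v in y]  # strictly increasing
        fit_tr = fit_cumulative_link(transformed, t)
        assert fit_tr.beta_treatment == pytest.approx(fit_raw.beta_treatment, abs=1e-6)
        assert fit_tr.loglik == pytest.approx(fit_raw.loglik, abs=1e-6)

    def test_expected_score_is_probability_weighted_level_sum(self, oracle_dataset):
        y, t = oracle_dataset
        fit = fit_cumulative_link(list(y), t)
        pred = typical_patient_prediction(fit)
        for arm in (0.0, 1.0):
            probs = fit.category_probs(arm)
            assert probs.sum() == pytest.approx(1.0)
            assert pred[arm] == pytest.approx(float(probs @ fit.level_values))


class TestTwoCategoryReduction:
    def test_equals_binary_logistic_mle(self):
        rng = np.random.default_rng(3)
        n = 300
        t = rng.integers(0, 2, n).astype(float)
        base = rng.normal(0, 1, n)
        y = (rng.uniform(size=n) < sm.families.links.Logit().inverse(
            -0.3 + 0.9 * t + 0.5 * base)).astype(float)
        fit = fit_cumulative_link(list(y), t, base, n_knots=0)
        logit = sm.Logit(y, sm.add_constant(np.column_stack([t, base]))).fit(disp=False)
        assert fit.beta_treatment == pytest.approx(logit.params[1], abs=1e-6)
        assert float(fit.beta_covariates[0]) == pytest.approx(logit.params[2], abs=1e-6)
        assert fit.thresholds[0] == pytest.approx(-logit.params[0], abs=1e-6)
        assert fit.loglik == pytest.approx(logit.llf, abs=1e-8)
        assert fit.se_treatment == pytest.approx(logit.bse[1], rel=1e-4)


def test_parameter_recovery_at_large_n():
    """With data simulated from the model, beta lands within 3 s.e. of truth."""
    true_beta = np.log(2.21)
    rng = np.random.default_rng(20)
    n = 5000
    t = rng.integers(0, 2, n).astype(float)
    base = rng.normal(0, 1, n)
    latent = true_beta * t + 0.6 * base + rng.logistic(0, 1, n)
    y = np.searchsorted([-1.5, -0.5, 0.5, 1.5], latent).astype(float)
    fit = fit_cumulative_link(list(y), t, base, n_knots=0)
    assert fit.converged
    assert abs(fit.beta_treatment - true_beta) < 3 * fit.se_treatment
    assert wald_p_value(fit) < 1e-6


def test_statsmodels_ordered_model_cross_check():
    """Independent library fit of the same likelihood agrees closely."""
    rng = np.random.default_rng(9)
    n = 400
    t = rng.integers(0, 2, n).astype(float)
    base = rng.normal(0, 1, n)
    latent = 0.7 * t + 0.4 * base + rng.logistic(0, 1, n)
    y = np.searchsorted([-1.0, 0.0, 1.0], latent)
    fit = fit_cumulative_link(list(y.astype(float)), t, base, n_knots=0)
    om = OrderedModel(y, np.column_stack([t, base]), distr="logit").fit(
        method="bfgs", disp=False)
    assert fit.beta_treatment == pytest.approx(om.params[0], abs=1e-4)
    assert fit.loglik == pytest.approx(om.llf, abs=1e-4)


class TestDegenerateInputs:
    def test_single_category_outcome_rejected(self):
        with pytest.raises(ValueError, match="single category"):
            fit_cumulative_link([1.0] * 10, [0, 1] * 5)

    def test_single_arm_rejected(self, oracle_dataset):
        y, _ = oracle_dataset
        with pytest.raises(ValueError, match="treatment"):
            fit_cumulative_link(list(y), np.zeros(len(y)))

    def test_complete_separation_flagged_not_raised(self):
        y = [0.0] * 10 + [1.0] * 10
        t = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_cumulative_link(y, t)
        assert not fit.converged
        assert fit.message != ""
        with pytest.raises(ValueError):
            odds_ratio(fit)


def test_monotone_likelihood_ascent(oracle_dataset):
    """The optimizer's accepted iterates never decrease the likelihood."""
    y, t = oracle_dataset
    fit = fit_cumulative_link(list(y), t)
    nll = np.array(fit.nll_path)
    assert len(nll) >= 2
    assert np.all(np.diff(nll) <= 1e-9)


def test_null_treatment_effect_predicts_equal_arms():
    fit = CumulativeLinkFit(
        categories=[0.0, 1.0, 2.0],
        level_values=np.array([0.0, 1.0, 2.0]),
        thresholds=np.array([-0.5, 0.8]),
        beta_treatment=0.0,
        beta_covariates=np.empty(0),
        covariance=np.eye(3),
        loglik=-1.0,
        n=10,
        converged=True,
    )
    pred = typical_patient_prediction(fit)
    assert pred[0.0] == pytest.approx(pred[1.0])
    assert np.exp(fit.beta_treatment) == 1.0


def test_overrides_occupy_top_ordinal_levels():
    outcome = [0.0, 1.5, "acs", 3.0, "death", "unblinding", 1.5]
    codes, categories, values = encode_ordinal(outcome)
    assert categories == [0.0, 1.5, 3.0, "unblinding", "acs", "death"]
    assert list(values) == [0.0, 1.5, 3.0, 4.0, 5.0, 6.0]
    assert codes.tolist() == [0, 1, 4, 2, 5, 3, 1]


class TestRestrictedCubicSpline:
    def test_knot_count_rule(self):
        x = np.linspace(0, 1, 100)
        basis, design = rcs_basis(x, n_knots=3)
        assert design.shape == (100, 2)
        basis5, design5 = rcs_basis(x, n_knots=5)
        assert design5.shape == (100, 4)

    def test_too_many_knots_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rcs_basis([0.0, 1.0, 2.0], n_knots=4)

    def test_smoothness_at_knots(self):
        """Value, first and second derivative are continuous at each knot."""
        x = np.linspace(0, 1, 2001)
        basis, _ = rcs_basis(x, n_knots=4)
        h = 1e-5
        for knot in basis.knots:
            for order in range(3):
                left = _numeric_derivative(basis, knot - 50 * h, order, h)
                right = _numeric_derivative(basis, knot + 50 * h, order, h)
                np.testing.assert_allclose(left, right, rtol=0, atol=2e-2)

    def test_linear_beyond_boundary_knots(self):
        x = np.linspace(0, 1, 500)
        basis, _ = rcs_basis(x, n_knots=4)
        far = np.array([2.0, 3.0, 4.0])
        cols = basis.transform(far)
        for j in range(cols.shape[1]):
            slopes = np.diff(cols[:, j]) / np.diff(far)
            assert slopes[0] == pytest.approx(slopes[1], abs=1e-9)

    def test_recovers_piecewise_cubic_function(self):
        """A natural cubic spline target is reproduced with ~zero residual."""
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 10, 400))
        basis, design = rcs_basis(x, n_knots=5)
        coef_true = np.array([1.0, -2.0, 3.0, -1.5])
        y = 0.7 + design @ coef_true
        X = sm.add_constant(design)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        assert np.max(np.abs(resid)) < 1e-8


def _numeric_derivative(basis, x0, order, h):
    if order == 0:
        return basis.transform([x0])[0]
    if order == 1:
        return (basis.transform([x0 + h])[0] - basis.transform([x0 - h])[0]) / (2 * h)
    return (
        basis.transform([x0 + h])[0]
        - 2 * basis.transform([x0])[0]
        + basis.transform([x0 - h])[0]
    ) / h**2
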
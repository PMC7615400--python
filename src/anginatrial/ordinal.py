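"""Ordinal analysis of covariance via a cumulative probability model.

The primary endpoint is analyzed with a proportional-odds cumulative
link model: for ordered outcome categories ``c_1 < ... < c_K``,

    P(Y <= c_k | x) = F(alpha_k - x beta),   F = logistic,

with one strictly increasing threshold per internal category boundary
and covariate effects shared across boundaries.  Because the likelihood
depends on the outcome only through its ordering, no distributional
assumption is placed on the score itself, and distinct observed values
can each form their own category (continuous-ordinal treatment).
Clinical override categories (unblinding < acute coronary syndrome <
death) sit above every numeric score level.

The model is fit by quasi-Newton maximization of the exact
log-likelihood with analytic gradients, using the reparameterization
``alpha_k = alpha_1 + sum_{j<=k} exp(delta_j)`` to enforce increasing
thresholds.  Standard errors come from the inverse observed information
at the maximum.  Baseline adjustment uses a restricted cubic (natural)
spline basis so the covariate effect need not be linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .scoring import OVERRIDES, is_override

__all__ = [
    "SplineBasis",
    "CumulativeLinkFit",
    "rcs_basis",
    "fit_cumulative_link",
    "odds_ratio",
    "typical_patient_prediction",
    "encode_ordinal",
]

# Harrell-style default knot quantiles by knot count
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class SplineBasis:
    """Restricted cubic spline basis defined by its knots.

    The basis has ``len(knots) - 1`` columns: the identity plus
    ``len(knots) - 2`` restricted truncated-power cubic terms.  The
    spline is linear beyond the boundary knots and has continuous value,
    first and second derivative everywhere.
    """

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if len(k) < 3:
            raise ValueError("restricted cubic splines need >= 3 knots")
        if np.any(np.diff(k) <= 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        """Design columns for covariate values ``x``, shape (n, k-1)."""
        x = np.asarray(x, dtype=float)
        t = np.asarray(self.knots, dtype=float)
        k = len(t)
        norm = (t[-1] - t[0]) ** 2
        cols = [x]
        for j in range(k - 2):
            term = (
                np.clip(x - t[j], 0, None) ** 3
                - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
                + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
            )
            cols.append(term / norm)
        return np.column_stack(cols)


def rcs_basis(x, n_knots: int = 4) -> tuple[SplineBasis, np.ndarray]:
    """Restricted cubic spline basis with knots at standard quantiles.

    Returns the basis object and the design columns for ``x``.
    Rejects requests for more knots than distinct covariate values.
    """
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    if n_knots > len(distinct):
        raise ValueError(
            f"n_knots={n_knots} exceeds the {len(distinct)} distinct values"
        )
    if n_knots in _KNOT_QUANTILES:
        q = np.asarray(_KNOT_QUANTILES[n_knots])
    else:
        q = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(x, q)
    if len(np.unique(knots)) < n_knots:
        # heavy ties at quantiles: fall back to distinct-value placement
        knots = np.quantile(distinct, q)
        knots = np.unique(knots)
        if len(knots) < 3:
            raise ValueError("could not place >= 3 distinct knots")
    basis = SplineBasis(tuple(knots))
    return basis, basis.transform(x)


def encode_ordinal(outcome, max_numeric_levels: int | None = None):
    """Map mixed numeric/override outcomes to ordered category codes.

    Numeric values are ordered by magnitude; override categories are
    appended above all numeric levels in severity order.  Each category
    carries a representative numeric ``level value`` used only for
    expected-score summaries: a numeric category represents itself and
    the overrides take values one, two and three units above the numeric
    maximum.

    With ``max_numeric_levels`` set, numeric values are grouped into at
    most that many quantile bins (each represented by its mean), for
    small samples where one category per distinct value is too fine.

    Returns ``(codes, categories, level_values)``.
    """
    outcome = list(outcome)
    numeric = sorted({float(v) for v in outcome if not is_override(v)})
    if max_numeric_levels is not None and len(numeric) > max_numeric_levels:
        vals = np.array([float(v) for v in outcome if not is_override(v)])
        edges = np.quantile(vals, np.linspace(0, 1, max_numeric_levels + 1))
        edges = np.unique(edges)
        bin_of = np.clip(np.searchsorted(edges, vals, side="right") - 1,
                         0, len(edges) - 2)
        remap = {}
        reps = []
        for b in range(len(edges) - 1):
            members = vals[bin_of == b]
            if len(members):
                reps.append(float(members.mean()))
                for v in np.unique(members):
                    remap[float(v)] = len(reps) - 1
        numeric_index = remap
        numeric_values = reps
    else:
        numeric_index = {v: i for i, v in enumerate(numeric)}
        numeric_values = numeric

    overrides_present = [c for c in OVERRIDES if c in outcome]
    categories = list(numeric_values) + overrides_present
    base = max(numeric_values) if numeric_values else 0.0
    level_values = np.array(
        list(numeric_values) + [base + 1.0 + i for i in range(len(overrides_present))],
        dtype=float,
    )
    codes = np.array(
        [
            len(numeric_values) + overrides_present.index(v)
            if is_override(v)
            else numeric_index[float(v)]
            for v in outcome
        ],
        dtype=np.int64,
    )
    return codes, categories, level_values


@dataclass
class CumulativeLinkFit:
    """Fitted proportional-odds cumulative link model.

    ``beta_treatment`` is the log odds ratio for the treatment indicator
    as coded by the caller; in the trial pipeline the indicator marks
    the placebo arm, so a positive coefficient (odds ratio above 1)
    means placebo patients have higher — worse — scores.
    """

    categories: list
    level_values: np.ndarray
    thresholds: np.ndarray
    beta_treatment: float
    beta_covariates: np.ndarray
    covariance: np.ndarray
    loglik: float
    n: int
    converged: bool
    message: str = ""
    spline: SplineBasis | None = None
    baseline_range: tuple[float, float] | None = None
    nll_path: list = field(default_factory=list)

    @property
    def se_treatment(self) -> float:
        k = len(self.thresholds)
        return float(np.sqrt(self.covariance[k, k]))

    def _baseline_columns(self, baseline_value: float) -> np.ndarray:
        if self.beta_covariates.size == 0:
            return np.empty(0)
        if self.spline is not None:
            return self.spline.transform([baseline_value])[0]
        return np.array([baseline_value])

    def category_probs(self, treatment: float, baseline_value: float | None = None) -> np.ndarray:
        """Fitted category probabilities for one covariate profile."""
        eta = self.beta_treatment * treatment
        if self.beta_covariates.size:
            if baseline_value is None:
                raise ValueError("fit includes a baseline effect: baseline_value required")
            eta += float(self._baseline_columns(baseline_value) @ self.beta_covariates)
        cum = special.expit(self.thresholds - eta)
        cum = np.concatenate([cum, [1.0]])
        return np.diff(cum, prepend=0.0)


def _nll_grad(theta_raw, y, X, K):
    """Negative log-likelihood and gradient in raw parameters.

    Raw vector: ``[alpha_1, delta_2..delta_{K-1}, beta]`` with
    ``alpha_k = alpha_1 + sum exp(delta)`` guaranteeing ordered
    thresholds for any real input.
    """
    p = X.shape[1]
    a1 = theta_raw[0]
    deltas = theta_raw[1 : K - 1]
    beta = theta_raw[K - 1 :]
    steps = np.exp(deltas)
    alpha = a1 + np.concatenate([[0.0], np.cumsum(steps)])

    eta = X @ beta if p else np.zeros(len(y))
    upper = np.where(y < K - 1, alpha[np.minimum(y, K - 2)], np.inf)
    lower = np.where(y > 0, alpha[np.maximum(y - 1, 0)], -np.inf)
    FU = special.expit(upper - eta)
    FL = special.expit(lower - eta)
    P = np.clip(FU - FL, 1e-300, None)
    nll = -np.sum(np.log(P))

    fU = np.where(np.isfinite(upper), FU * (1 - FU), 0.0)
    fL = np.where(np.isfinite(lower), FL * (1 - FL), 0.0)
    inv = 1.0 / P
    # d nll / d alpha_k: upper edge of category k and lower edge of k+1
    g_alpha = np.zeros(K - 1)
    np.add.at(g_alpha, np.minimum(y, K - 2), np.where(y < K - 1, -fU * inv, 0.0))
    np.add.at(g_alpha, np.maximum(y - 1, 0), np.where(y > 0, fL * inv, 0.0))
    w = (fU - fL) * inv  # = d nll / d eta_i
    g_beta = X.T @ w if p else np.empty(0)

    g_raw = np.empty_like(theta_raw)
    g_raw[0] = g_alpha.sum()
    if K > 2:
        tail = np.cumsum(g_alpha[::-1])[::-1]  # sum_{k>=j} g_alpha[k]
        g_raw[1 : K - 1] = steps * tail[1:]
    g_raw[K - 1 :] = g_beta
    return nll, g_raw


def _grad_original(theta, y, X, K):
    """Gradient of the NLL in original (alpha, beta) coordinates."""
    p = X.shape[1]
    alpha = theta[: K - 1]
    beta = theta[K - 1 :]
    eta = X @ beta if p else np.zeros(len(y))
    upper = np.where(y < K - 1, alpha[np.minimum(y, K - 2)], np.inf)
    lower = np.where(y > 0, alpha[np.maximum(y - 1, 0)], -np.inf)
    FU = special.expit(upper - eta)
    FL = special.expit(lower - eta)
    P = np.clip(FU - FL, 1e-300, None)
    fU = np.where(np.isfinite(upper), FU * (1 - FU), 0.0)
    fL = np.where(np.isfinite(lower), FL * (1 - FL), 0.0)
    inv = 1.0 / P
    g_alpha = np.zeros(K - 1)
    np.add.at(g_alpha, np.minimum(y, K - 2), np.where(y < K - 1, -fU * inv, 0.0))
    np.add.at(g_alpha, np.maximum(y - 1, 0), np.where(y > 0, fL * inv, 0.0))
    w = (fU - fL) * inv
    g_beta = X.T @ w if p else np.empty(0)
    return np.concatenate([g_alpha, g_beta])


def _observed_information(theta, y, X, K):
    """Hessian of the NLL by central differences of the analytic gradient."""
    d = len(theta)
    H = np.zeros((d, d))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(d):
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        H[:, j] = (_grad_original(tp, y, X, K) - _grad_original(tm, y, X, K)) / (2 * h[j])
    return (H + H.T) / 2


def fit_cumulative_link(
    outcome,
    treatment,
    baseline=None,
    n_knots: int = 4,
    max_numeric_levels: int | None = None,
    gtol: float = 1e-8,
) -> CumulativeLinkFit:
    """Fit the ordinal analysis of covariance.

    Parameters
    ----------
    outcome : sequence of float or override category
        Per-patient follow-up summaries; distinct numeric values each
        form an ordinal category, with overrides on top.
    treatment : binary sequence
        Treatment indicator.  In the trial pipeline 1 marks placebo so
        that an odds ratio above 1 means worse scores under placebo.
    baseline : sequence of float, optional
        Baseline covariate (pre-randomization score).  Entered through a
        restricted cubic spline with ``n_knots`` knots; pass
        ``n_knots=0`` (or 1) for a linear adjustment.  Falls back to
        linear when the covariate has too few distinct values.
    max_numeric_levels : int, optional
        Quantile-bin the numeric outcome levels for small samples.
    gtol : float
        Target infinity-norm of the gradient at the maximum.

    Complete separation (or other failure to converge) is reported via
    ``fit.converged`` and ``fit.message`` rather than raised.
    """
    y, categories, level_values = encode_ordinal(outcome, max_numeric_levels)
    treatment = np.asarray(treatment, dtype=float)
    K = len(categories)
    if K < 2:
        raise ValueError("outcome has a single category; ordinal model undefined")
    if len(np.unique(treatment)) < 2:
        raise ValueError("both treatment groups must be represented")

    cols = [treatment]
    spline = None
    baseline_range = None
    if baseline is not None:
        baseline = np.asarray(baseline, dtype=float)
        baseline_range = (float(baseline.min()), float(baseline.max()))
        distinct = len(np.unique(baseline))
        if n_knots and n_knots >= 3 and distinct >= max(n_knots, 3):
            try:
                spline, design = rcs_basis(baseline, n_knots)
                cols.append(design)
            except ValueError:
                cols.append(baseline[:, None])
        else:
            cols.append(baseline[:, None])
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    n, p = X.shape

    # starting values: empirical cumulative logits, beta = 0
    counts = np.bincount(y, minlength=K)
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    alpha0 = special.logit(cum)
    steps0 = np.clip(np.diff(alpha0), 1e-3, None)
    theta0 = np.concatenate([[alpha0[0]], np.log(steps0), np.zeros(p)])

    nll_path: list[float] = []

    def fun(t):
        v, g = _nll_grad(t, y, X, K)
        return v, g

    def cb(tk):
        nll_path.append(_nll_grad(tk, y, X, K)[0])

    res = optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": 2000, "maxfun": 20000, "ftol": 1e-14, "gtol": gtol},
    )
    a1 = res.x[0]
    alpha = a1 + np.concatenate([[0.0], np.cumsum(np.exp(res.x[1 : K - 1]))])
    beta = res.x[K - 1 :]
    theta = np.concatenate([alpha, beta])
    grad = _grad_original(theta, y, X, K)
    gnorm = float(np.max(np.abs(grad)))

    converged = bool(np.isfinite(res.fun)) and gnorm < max(1e4 * gtol, 1e-4 * n)
    message = ""
    H = _observed_information(theta, y, X, K)
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or cov[K - 1, K - 1] <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        converged = False
        message = "singular information matrix (possible complete separation)"
    if np.abs(beta[0]) > 15:
        converged = False
        message = "treatment coefficient diverged (complete separation)"
    if not converged and not message:
        message = f"gradient norm {gnorm:.2e} above tolerance: {res.message}"

    return CumulativeLinkFit(
        categories=categories,
        level_values=level_values,
        thresholds=alpha,
        beta_treatment=float(beta[0]),
        beta_covariates=beta[1:],
        covariance=cov,
        loglik=float(-res.fun),
        n=n,
        converged=converged,
        message=message,
        spline=spline,
        baseline_range=baseline_range,
        nll_path=nll_path,
    )


def odds_ratio(fit: CumulativeLinkFit, conf_level: float = 0.95):
    """Treatment odds ratio with Wald confidence interval.

    ``OR = exp(beta_treatment)``; the interval is
    ``exp(beta +/- z * se)`` from the observed information.
    """
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    z = stats.norm.ppf(0.5 + conf_level / 2)
    se = fit.se_treatment
    b = fit.beta_treatment
    return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))


def wald_p_value(fit: CumulativeLinkFit) -> float:
    """Two-sided Wald p-value for the treatment effect."""
    z = fit.beta_treatment / fit.se_treatment
    return float(2 * stats.norm.sf(abs(z)))


def typical_patient_prediction(
    fit: CumulativeLinkFit, baseline_value: float | None = None
) -> dict[float, float]:
    """Model-derived expected score per arm for a reference patient.

    For each treatment level the expected outcome is the probability-
    weighted mean of the category level values,
    ``sum_k value_k P(level_k | arm, baseline)``.  The reference
    ("typical") patient is conventionally the median baseline for score
    endpoints.  Returns ``{0.0: expectation, 1.0: expectation}`` keyed
    by treatment indicator.
    """
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    if (
        baseline_value is not None
        and fit.baseline_range is not None
        and not (fit.baseline_range[0] <= baseline_value <= fit.baseline_range[1])
    ):
        warnings.warn(
            f"baseline value {baseline_value} outside observed range "
            f"{fit.baseline_range}; prediction is an extrapolation",
            stacklevel=2,
        )
    out = {}
    for arm in (0.0, 1.0):
        probs = fit.category_probs(arm, baseline_value)
        out[arm] = float(np.sum(fit.level_values * probs))
    return out
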
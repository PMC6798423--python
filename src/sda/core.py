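"""Two-part semi-parametric model for a single feature.

A feature's abundance across samples is a mixture of a point mass at zero
and a continuous distribution on positive values.  The zero part follows a
logistic regression

    log(pi_i / (1 - pi_i)) = gamma0 + gamma . x_i,

where ``pi_i = Pr(Y_i = 0)``.  The non-zero part follows a semi-parametric
log-linear (accelerated failure time) model

    log(Y_i) = beta . x_i + eps_i,

where the errors ``eps_i`` share a completely unspecified density.  The
unknown density is replaced by a Gaussian kernel density estimate of the
residuals, which turns the likelihood into a smooth finite-dimensional
objective.  A likelihood-ratio test comparing the full fit to the fit with
the tested covariate removed from both parts (chi-square, 2 df when both
parts are informative) screens features for differential abundance.

The non-zero model carries no intercept: the location of the error
distribution is not identifiable alongside one and is absorbed by the
kernel density estimate, so ``beta`` coefficients are log fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "FeatureVector",
    "DesignMatrix",
    "ZeroPartFit",
    "NonzeroPartFit",
    "FeatureFit",
    "FeatureTestResult",
    "DegenerateFeatureError",
    "NonIdentifiableError",
    "gaussian_kernel",
    "select_bandwidth",
    "fit_zero_part",
    "smoothed_loglik_nonzero",
    "fit_nonzero_part",
    "fit_feature",
    "fit_joint",
    "lrt_test",
    "test_feature",
]

#: |coefficient| beyond which a logistic fit is declared (quasi-)separated.
SEPARATION_CAP = 15.0

#: LRT values in (-LRT_TOL, 0) are clipped to zero; smaller negatives raise.
LRT_TOL = 1e-6

_GRAD_TOL = 1e-8
_MAX_ITER = 500


class DegenerateFeatureError(ValueError):
    """Feature has too little non-zero information to fit the continuous part."""


class NonIdentifiableError(ValueError):
    """A covariate column is constant over the samples entering a fit."""


# ---------------------------------------------------------------------------
# Containers


@dataclass
class FeatureVector:
    """Observed abundances of one feature across N samples.

    ``delta[i] = 1`` iff ``y[i] == 0``; zeros are data (absence or below the
    detection limit), not missing values.
    """

    feature_id: str
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.size < 2:
            raise ValueError("feature needs a 1-d vector of length >= 2")
        if np.any(self.y < 0) or not np.all(np.isfinite(self.y)):
            raise ValueError(f"feature {self.feature_id!r}: abundances must be finite and non-negative")

    @property
    def delta(self) -> np.ndarray:
        """Zero indicator, delta_i = I{y_i = 0}."""
        return (self.y == 0).astype(float)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.y > 0))


@dataclass
class DesignMatrix:
    """N x Q covariate matrix with one designated test covariate.

    ``test_index`` is the 0-based column of the covariate under test.
    The intercept is implicit (added by the zero-part fit, absent from the
    non-zero part by construction).
    """

    X: np.ndarray
    test_index: int = 0
    sample_ids: Optional[Sequence[str]] = None
    covariate_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-d (N samples x Q covariates)")
        if self.X.shape[1] and not 0 <= self.test_index < self.X.shape[1]:
            raise ValueError("test_index out of range")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(self.X.shape[0])]
        if self.covariate_names is None:
            self.covariate_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def drop_test(self) -> "DesignMatrix":
        """Design with the test covariate removed (the null model design)."""
        keep = [j for j in range(self.X.shape[1]) if j != self.test_index]
        return DesignMatrix(
            X=self.X[:, keep],
            test_index=0 if keep else 0,
            sample_ids=self.sample_ids,
            covariate_names=[self.covariate_names[j] for j in keep],
        ) if keep else DesignMatrix(
            X=np.empty((self.X.shape[0], 0)),
            test_index=0,
            sample_ids=self.sample_ids,
            covariate_names=[],
        )


@dataclass
class ZeroPartFit:
    gamma0: float
    gamma: np.ndarray
    loglik: float
    separated: bool = False


@dataclass
class NonzeroPartFit:
    beta: np.ndarray
    h: float
    loglik: float
    n_nonzero: int
    converged: bool = True


@dataclass
class FeatureFit:
    """Full and null two-part fits for one feature, sharing the bandwidth."""

    feature_id: str
    mode: str  # both_parts | nonzero_only | zero_only | skipped
    h: Optional[float]
    full_zero: Optional[ZeroPartFit]
    full_nonzero: Optional[NonzeroPartFit]
    null_zero: Optional[ZeroPartFit]
    null_nonzero: Optional[NonzeroPartFit]
    flags: list = field(default_factory=list)

    def loglik(self, which: str) -> float:
        """Total log-likelihood of the ``'full'`` or ``'null'`` model.

        The Jacobian term ``-sum(log Y_i)`` over non-zero samples is a
        parameter-free constant and is excluded throughout; it cancels
        exactly in every likelihood-ratio comparison.
        """
        zero, nonzero = (
            (self.full_zero, self.full_nonzero)
            if which == "full"
            else (self.null_zero, self.null_nonzero)
        )
        total = 0.0
        if zero is not None:
            total += zero.loglik
        if nonzero is not None:
            total += nonzero.loglik
        return total


@dataclass
class FeatureTestResult:
    feature_id: str
    mode: str
    gamma0_hat: float = np.nan
    gamma_hat_q: float = np.nan
    beta_hat_q: float = np.nan
    h: float = np.nan
    lrt: float = np.nan
    df: int = 0
    pvalue: float = np.nan
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Kernel and bandwidth


def gaussian_kernel(u):
    """Standard Gaussian kernel K(u) = (2*pi)^(-1/2) exp(-u^2/2)."""
    u = np.asarray(u, dtype=float)
    return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)


def select_bandwidth(log_nonzero: np.ndarray, n_total: int, scale: float = 1.144) -> float:
    """Rule-of-thumb bandwidth h = 1.144 * sigma_hat * N^(-1/5).

    ``sigma_hat`` is the sample standard deviation (N-1 denominator) of the
    non-zero log abundances; ``n_total`` is the total number of samples
    (zeros included), N = 2n in a balanced two-group design.
    """
    log_nonzero = np.asarray(log_nonzero, dtype=float)
    if log_nonzero.size < 2:
        raise DegenerateFeatureError("bandwidth needs >= 2 non-zero values")
    sd = float(np.std(log_nonzero, ddof=1))
    if sd <= 0:
        raise DegenerateFeatureError("bandwidth undefined: constant non-zero log values")
    return scale * sd * float(n_total) ** (-0.2)


# ---------------------------------------------------------------------------
# Zero part: logistic regression


def _logistic_loglik_grad(theta: np.ndarray, Xd: np.ndarray, delta: np.ndarray):
    eta = Xd @ theta
    # log(1+exp(eta)) computed stably
    ll = float(np.sum(delta * eta) - np.sum(np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = Xd.T @ (delta - p)
    return ll, grad, p


def fit_zero_part(delta: np.ndarray, X: np.ndarray) -> ZeroPartFit:
    """Maximum-likelihood logistic regression of the zero indicator on (1, X).

    Newton iteration with step-halving; if the likelihood is monotone
    (complete or quasi-complete separation) coefficients diverge, in which
    case the fit is recomputed under a |coef| <= 15 box and flagged
    ``separated``.  Raises :class:`DegenerateFeatureError` when ``delta`` is
    constant (the zero part carries no information).
    """
    delta = np.asarray(delta, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if delta.shape[0] != X.shape[0]:
        raise ValueError("delta and X have mismatched lengths")
    if np.all(delta == delta[0]):
        raise DegenerateFeatureError("all-zero or all-non-zero feature: zero part non-informative")

    Xd = np.column_stack([np.ones(len(delta)), X])
    theta = np.zeros(Xd.shape[1])
    ll, grad, p = _logistic_loglik_grad(theta, Xd, delta)
    separated = False
    for _ in range(100):
        if np.max(np.abs(grad)) < 1e-10:
            break
        W = p * (1.0 - p)
        H = Xd.T @ (Xd * W[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step halving to guarantee ascent
        t = 1.0
        for _ in range(30):
            new = theta + t * step
            ll_new, grad_new, p_new = _logistic_loglik_grad(new, Xd, delta)
            if ll_new >= ll - 1e-14:
                theta, ll, grad, p = new, ll_new, grad_new, p_new
                break
            t *= 0.5
        else:
            separated = True
            break
        if np.max(np.abs(theta)) > SEPARATION_CAP:
            separated = True
            break
    else:
        if np.max(np.abs(grad)) > 1e-6:
            separated = True

    if separated:
        # capped fit: maximize under the box so the LRT contribution is finite
        res = optimize.minimize(
            lambda t: -_logistic_loglik_grad(t, Xd, delta)[0],
            np.clip(theta, -SEPARATION_CAP, SEPARATION_CAP),
            jac=lambda t: -_logistic_loglik_grad(t, Xd, delta)[1],
            method="L-BFGS-B",
            bounds=[(-SEPARATION_CAP, SEPARATION_CAP)] * Xd.shape[1],
            options={"maxiter": _MAX_ITER, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta = res.x
        ll = -res.fun

    return ZeroPartFit(gamma0=float(theta[0]), gamma=theta[1:].copy(), loglik=ll, separated=separated)


# ---------------------------------------------------------------------------
# Non-zero part: kernel-smoothed likelihood


def smoothed_loglik_nonzero(beta, log_y: np.ndarray, X_nz: np.ndarray, h: float) -> float:
    """Kernel-smoothed log-likelihood of the non-zero observations.

    With residuals ``r_i = log(y_i) - beta . x_i`` over the ``N+`` non-zero
    samples, returns

        sum_i log[ (1 / (N+ h)) * sum_j K((r_j - r_i) / h) ],

    the log of the leave-in kernel density estimate of each residual under
    the density estimated from all residuals (the self term j = i is
    included).  The kernel sum runs over non-zero observations only, where
    residuals exist, making the density estimate proper.  The Jacobian term
    ``-sum log(y_i)`` is constant in the parameters and excluded.
    """
    ll, _ = _smoothed_nonzero_objective(np.atleast_1d(np.asarray(beta, dtype=float)),
                                        log_y, X_nz, h, want_grad=False)
    return ll


def _smoothed_nonzero_objective(beta, log_y, X_nz, h, want_grad=True):
    r = log_y - (X_nz @ beta if X_nz.shape[1] else 0.0)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite residuals in smoothed likelihood")
    n = r.shape[0]
    D = (r[None, :] - r[:, None]) / h  # D[i, j] = (r_j - r_i) / h
    K = np.exp(-0.5 * D * D)  # unnormalized Gaussian kernel
    S = K.sum(axis=1)
    # log f_i = log(S_i) - log(n h sqrt(2 pi))
    ll = float(np.sum(np.log(S)) - n * np.log(n * h * np.sqrt(2.0 * np.pi)))
    if not want_grad:
        return ll, None
    if X_nz.shape[1] == 0:
        return ll, np.zeros(0)
    G = -(D * K) / h  # d K(D_ij) / d r_j direction, up to the sign split below
    row = G.sum(axis=1)
    num = X_nz * row[:, None] - G @ X_nz
    grad = (num / S[:, None]).sum(axis=0)
    return ll, grad


def fit_nonzero_part(log_y: np.ndarray, X_nz: np.ndarray, h: float) -> NonzeroPartFit:
    """Maximize the kernel-smoothed likelihood over beta (no intercept).

    BFGS with analytic gradient from two warm starts, beta = 0 and the
    least-squares slope of ``log_y`` on ``(1, X_nz)``; the start reaching the
    higher likelihood wins, ties broken by smaller ||beta||.
    """
    log_y = np.asarray(log_y, dtype=float)
    X_nz = np.asarray(X_nz, dtype=float)
    if X_nz.ndim == 1:
        X_nz = X_nz[:, None]
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    n, q = X_nz.shape
    if n < 2:
        raise DegenerateFeatureError("non-zero part needs >= 2 observations")
    if q and np.any(np.ptp(X_nz, axis=0) == 0):
        raise NonIdentifiableError("constant covariate column among non-zero samples")

    if q == 0:
        ll, _ = _smoothed_nonzero_objective(np.zeros(0), log_y, X_nz, h, want_grad=False)
        return NonzeroPartFit(beta=np.zeros(0), h=h, loglik=ll, n_nonzero=n, converged=True)

    # OLS warm start (slope of log_y on covariates, intercept absorbed)
    Xd = np.column_stack([np.ones(n), X_nz])
    ols = np.linalg.lstsq(Xd, log_y, rcond=None)[0][1:]
    starts = [np.zeros(q), ols]

    def neg(b):
        ll, g = _smoothed_nonzero_objective(b, log_y, X_nz, h)
        return -ll, -g

    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            neg, x0, jac=True, method="BFGS",
            options={"gtol": _GRAD_TOL, "maxiter": _MAX_ITER},
        )
        ll = -res.fun
        ok = bool(res.success) or np.max(np.abs(res.jac)) < 1e-6
        any_ok = any_ok or ok
        cand = (ll, -float(np.linalg.norm(res.x)), res.x, ok)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    ll, _, beta, ok = best
    return NonzeroPartFit(beta=np.asarray(beta, dtype=float), h=h, loglik=ll,
                          n_nonzero=n, converged=any_ok)


# ---------------------------------------------------------------------------
# Per-feature orchestration


def classify_feature(feature: FeatureVector) -> str:
    """Which model parts are informative for this feature.

    both_parts:   zeros and >= 2 distinct non-zero values -> df 2
    nonzero_only: no zeros at all -> zero part dropped, df 1
    zero_only:    informative zero pattern but a degenerate continuous part
    skipped:      nothing testable (e.g. all zeros)
    """
    y = feature.y
    nz = y[y > 0]
    zero_informative = 0 < nz.size < y.size
    nonzero_ok = nz.size >= 2 and np.std(np.log(nz), ddof=1) > 0
    if nonzero_ok and zero_informative:
        return "both_parts"
    if nonzero_ok and nz.size == y.size:
        return "nonzero_only"
    if zero_informative:
        return "zero_only"
    return "skipped"


def _nonzero_design(feature: FeatureVector, design: DesignMatrix):
    mask = feature.y > 0
    return np.log(feature.y[mask]), design.X[mask], mask


def fit_feature(feature: FeatureVector, design: DesignMatrix) -> FeatureFit:
    """Fit the full and null two-part models for one feature.

    The null model removes the test covariate from both parts; other
    covariates are retained.  The bandwidth is computed once from the
    feature's non-zero log abundances (it does not involve beta) and shared
    by the two fits so the likelihood-ratio comparison is valid.
    """
    if feature.y.shape[0] != design.n_samples:
        raise ValueError("feature and design have mismatched sample counts")
    mode = classify_feature(feature)
    flags: list = []
    fit = FeatureFit(feature_id=feature.feature_id, mode=mode, h=None,
                     full_zero=None, full_nonzero=None,
                     null_zero=None, null_nonzero=None, flags=flags)
    if mode == "skipped":
        return fit

    null_design = design.drop_test()
    delta = feature.delta

    use_zero = mode in ("both_parts", "zero_only")
    use_nonzero = mode in ("both_parts", "nonzero_only")

    if use_nonzero:
        log_y, X_nz, _ = _nonzero_design(feature, design)
        h = select_bandwidth(log_y, design.n_samples)
        fit.h = h
        # covariates constant over the non-zero samples cannot enter the
        # continuous part; drop them from both fits so the comparison stays
        # nested (their contribution cancels in the LRT)
        variable = np.ptp(X_nz, axis=0) > 0
        if not variable[design.test_index]:
            flags.append("test_covariate_constant_in_nonzero")
            if mode == "both_parts":
                mode = fit.mode = "zero_only"
                use_nonzero = False
            else:
                return FeatureFit(feature_id=feature.feature_id, mode="skipped",
                                  h=h, full_zero=None, full_nonzero=None,
                                  null_zero=None, null_nonzero=None,
                                  flags=flags + ["no_testable_part"])
        if use_nonzero:
            if not np.all(variable):
                flags.append("dropped_constant_nonzero_covariates")
            keep_full = np.flatnonzero(variable)
            keep_null = np.array([j for j in keep_full if j != design.test_index], dtype=int)
            fit.full_nonzero = fit_nonzero_part(log_y, X_nz[:, keep_full], h)
            fit.null_nonzero = fit_nonzero_part(log_y, X_nz[:, keep_null], h)
            if not (fit.full_nonzero.converged and fit.null_nonzero.converged):
                flags.append("nonzero_optimizer_not_converged")
            # map beta back to original covariate positions
            beta_full = np.full(design.n_covariates, np.nan)
            beta_full[keep_full] = fit.full_nonzero.beta
            fit.full_nonzero.beta = beta_full

    if use_zero:
        fit.full_zero = fit_zero_part(delta, design.X)
        if null_design.n_covariates:
            fit.null_zero = fit_zero_part(delta, null_design.X)
        else:
            # intercept-only logistic: closed-form MLE
            pbar = float(np.mean(delta))
            g0 = np.log(pbar / (1.0 - pbar))
            ll = float(np.sum(delta) * np.log(pbar) + np.sum(1 - delta) * np.log(1 - pbar))
            fit.null_zero = ZeroPartFit(gamma0=g0, gamma=np.zeros(0), loglik=ll)
        if fit.full_zero.separated:
            flags.append("zero_part_separated")

    return fit


def lrt_test(fit: FeatureFit, design: Optional[DesignMatrix] = None) -> FeatureTestResult:
    """Likelihood-ratio test of the tested covariate from a fitted feature.

    LRT = -2 (loglik_null - loglik_full) summed over the informative parts;
    df = 2 when both parts contribute, 1 otherwise; the p-value is the
    chi-square upper tail.  Negative statistics within the numerical
    tolerance are clipped to zero; larger negatives indicate a broken
    nested comparison and raise.
    """
    res = FeatureTestResult(feature_id=fit.feature_id, mode=fit.mode,
                            flags=list(fit.flags))
    if fit.mode == "skipped":
        return res
    if (fit.full_nonzero is not None and fit.null_nonzero is not None
            and fit.full_nonzero.h != fit.null_nonzero.h):
        raise ValueError("mismatched bandwidths between full and null fits")

    lrt = -2.0 * (fit.loglik("null") - fit.loglik("full"))
    if lrt < -LRT_TOL:
        raise ValueError(f"negative LRT {lrt:.3e}: nested comparison violated")
    lrt = max(lrt, 0.0)
    df = 2 if fit.mode == "both_parts" else 1

    q = design.test_index if design is not None else 0
    if fit.full_zero is not None:
        res.gamma0_hat = fit.full_zero.gamma0
        res.gamma_hat_q = float(fit.full_zero.gamma[q])
    if fit.full_nonzero is not None:
        res.beta_hat_q = float(fit.full_nonzero.beta[q])
        res.h = fit.full_nonzero.h
    elif fit.h is not None:
        res.h = fit.h
    res.lrt = lrt
    res.df = df
    res.pvalue = float(chi2.sf(lrt, df))
    return res


def test_feature(feature: FeatureVector, design: DesignMatrix) -> FeatureTestResult:
    """Convenience wrapper: fit both models and run the LRT."""
    return lrt_test(fit_feature(feature, design), design)


# ---------------------------------------------------------------------------
# Joint objective (diagnostics)


def fit_joint(feature: FeatureVector, design: DesignMatrix):
    """Maximize the joint kernel-smoothed likelihood over all parameters.

    The joint log-likelihood factorizes into the logistic part in
    (gamma0, gamma) and the smoothed continuous part in beta (plus the
    parameter-free Jacobian constant), so this one-shot optimization must
    agree with the part-wise fits; it exists as a numerical cross-check of
    that factorization.  Returns ``(gamma0, gamma, beta, loglik)``.
    """
    if classify_feature(feature) != "both_parts":
        raise ValueError("joint fit requires an informative two-part feature")
    delta = feature.delta
    X = design.X
    Xd = np.column_stack([np.ones(len(delta)), X])
    log_y, X_nz, _ = _nonzero_design(feature, design)
    h = select_bandwidth(log_y, design.n_samples)
    q = design.n_covariates

    def neg(params):
        theta, beta = params[: q + 1], params[q + 1 :]
        ll_z, g_z, _ = _logistic_loglik_grad(theta, Xd, delta)
        ll_nz, g_nz = _smoothed_nonzero_objective(beta, log_y, X_nz, h)
        return -(ll_z + ll_nz), -np.concatenate([g_z, g_nz])

    res = optimize.minimize(neg, np.zeros(2 * q + 1), jac=True, method="BFGS",
                            options={"gtol": _GRAD_TOL, "maxiter": _MAX_ITER})
    params = res.x
    return float(params[0]), params[1 : q + 1].copy(), params[q + 1 :].copy(), float(-res.fun)
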
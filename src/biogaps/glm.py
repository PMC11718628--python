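"""Low-level GLM fitters used by the estimators.

Hand-rolled iteratively reweighted least squares for the weighted Poisson
log-link model, with both the model-based (inverse Fisher information) and
the heteroskedasticity-robust sandwich covariance A^-1 B A^-1, plus a
Newton fitter for logistic regression with an optional ridge penalty used
as the separation fallback.  These fits are deliberately self-contained —
they define the exact contract (tolerance 1e-10 on the coefficient change,
100 iterations) the estimators rely on — and are cross-checked against
statsmodels in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidDesignError

__all__ = ["GLMFit", "fit_poisson", "fit_logistic"]

_ETA_CLIP = 30.0  # exp(30) ~ 1e13: beyond any count scale these models see


@dataclass
class GLMFit:
    params: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    fitted: np.ndarray
    variance: str = "model"
    warnings: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _check_design(X: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[0] == 0:
        raise InvalidDesignError("design matrix must be 2-D with >= 1 row")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidDesignError("design matrix is rank deficient")


def fit_poisson(
    y,
    X,
    weights=None,
    variance: str = "model",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GLMFit:
    """Weighted Poisson ML (log link) via IRLS.

    Solves sum_i w_i (y_i - mu_i) x_i = 0 with mu = exp(X beta).  With
    ``variance='sandwich'`` the covariance is A^-1 B A^-1 where A is the
    weighted Fisher information X' diag(w mu) X and B the outer product of
    the weighted scores — valid when the weights are survey weights rather
    than precision weights.
    """
    if variance not in ("model", "sandwich"):
        raise ValueError(f"variance must be 'model' or 'sandwich', got {variance!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X)
    if len(y) != X.shape[0]:
        raise InvalidDesignError("y and X row counts differ")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")

    n, p = X.shape
    beta = np.zeros(p)
    # start from the intercept-only solution when an intercept column exists
    mu0 = max(float(np.sum(w * y) / np.sum(w)), 1e-8)
    const_cols = np.where(np.all(X == X[0], axis=0) & (X[0] != 0))[0]
    if const_cols.size:
        beta[const_cols[0]] = np.log(mu0) / X[0, const_cols[0]]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = w * mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise InvalidDesignError(f"singular IRLS system: {exc}") from exc
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step <= tol:
            converged = True
            break

    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    A = (X.T * (w * mu)) @ X
    A_inv = np.linalg.inv(A)
    if variance == "model":
        cov = A_inv
    else:
        score = w * (y - mu)
        B = (X.T * score**2) @ X
        cov = A_inv @ B @ A_inv
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(w * (y * eta - mu)))  # kernel; no factorial term
    warn = [] if converged else ["poisson_glm_not_converged"]
    return GLMFit(
        params=beta,
        cov=cov,
        converged=converged,
        n_iter=it,
        loglik=ll,
        fitted=mu,
        variance=variance,
        warnings=warn,
    )


def fit_logistic(
    y,
    X,
    ridge: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GLMFit:
    """Logistic regression by Newton-Raphson, optional ridge penalty.

    The ridge penalty (on all coefficients) keeps the Hessian invertible
    under complete separation; callers detect separation via divergence of
    the unpenalized fit and retry with a small ridge.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        prob = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(prob * (1.0 - prob), 1e-12)
        grad = X.T @ (y - prob) - ridge * beta
        H = (X.T * W) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise InvalidDesignError(f"singular Newton system: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(step)) <= tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:  # runaway: separation without ridge
            break

    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    prob = 1.0 / (1.0 + np.exp(-eta))
    W = np.maximum(prob * (1.0 - prob), 1e-12)
    H = (X.T * W) @ X + ridge * np.eye(p)
    cov = np.linalg.inv(H)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(y * np.log(np.clip(prob, 1e-300, 1)) +
                          (1 - y) * np.log(np.clip(1 - prob, 1e-300, 1))))
    warn = [] if converged else ["logistic_not_converged"]
    return GLMFit(
        params=beta,
        cov=cov,
        converged=converged,
        n_iter=it,
        loglik=ll,
        fitted=prob,
        variance="model",
        warnings=warn,
    )
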
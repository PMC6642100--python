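"""Internal Newton-Raphson fitters for logistic regression.

Fine-mapping evaluates tens of thousands of small logistic models per
analysis, so the per-fit overhead of a general GLM framework matters; this
module provides a minimal, deterministic IRLS/Newton solver with an explicit
ridge fallback for separated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

# Coefficients beyond this magnitude (log-odds per allele/copy) indicate
# (quasi-)separation: the MLE is diverging.
_SEP_COEF = 15.0


@dataclass(frozen=True)
class LogisticFit:
    """Result of a binary logistic maximum-likelihood (or ridge) fit."""

    beta: np.ndarray
    loglik: float
    cov: np.ndarray  # inverse observed information (ridge-adjusted if penalised)
    converged: bool
    separated: bool  # True when the ridge fallback was used
    n: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 60,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> LogisticFit:
    """Fit P(y=1|x) = expit(x beta) by Newton-Raphson with step halving.

    ``X`` must already contain an intercept column.  ``ridge`` adds a penalty
    -0.5*ridge*||beta||^2 to the log-likelihood (intercept included; the
    penalty is only used as a separation fallback and is small).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    beta = np.zeros(p)
    # start from the empirical logit for the intercept
    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    beta[0] = np.log(ybar / (1 - ybar))
    ll = _loglik(X, y, beta) - 0.5 * ridge * beta @ beta
    converged = False
    H = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving to guarantee ascent
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _loglik(X, y, cand) - 0.5 * ridge * cand @ cand
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if ll_new - ll < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = (X.T * w) @ X + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogisticFit(
        beta=beta,
        loglik=float(_loglik(X, y, beta)),
        cov=cov,
        converged=converged,
        separated=False,
        n=n,
    )


def fit_logistic_safe(X: np.ndarray, y: np.ndarray) -> LogisticFit:
    """ML fit, falling back to a small ridge penalty under separation.

    The fallback keeps model searches total: a separated model gets a finite,
    penalised log-likelihood and is flagged via ``separated``.
    """
    fit = fit_logistic(X, y)
    if fit.converged and np.all(np.abs(fit.beta) < _SEP_COEF):
        return fit
    n = X.shape[0]
    ridge = max(1e-4 * n, 1.0)
    pen = fit_logistic(X, y, ridge=ridge)
    return LogisticFit(
        beta=pen.beta,
        loglik=pen.loglik,
        cov=pen.cov,
        converged=pen.converged,
        separated=True,
        n=n,
    )


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())
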
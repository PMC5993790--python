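"""Small, fast logistic-regression primitives.

The permutation-based multiple-testing correction re-fits the burden logistic
model tens of thousands of times per gene, so the fits here are a lean
Newton/IRLS loop on dense numpy arrays instead of a full GLM framework. The
unit tests cross-check coefficients, Wald statistics and score tests against
statsmodels on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SeparationError(RuntimeError):
    """Raised when the likelihood is unbounded (quasi-complete separation)."""


@dataclass
class LogitFit:
    beta: np.ndarray          # coefficients, X column order
    cov: np.ndarray           # inverse observed information
    mu: np.ndarray            # fitted probabilities
    converged: bool
    n_iter: int


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 60,
                 tol: float = 1e-10) -> LogitFit:
    """Maximum-likelihood logistic fit of y on columns of X (no intercept added).

    Raises
    ------
    SeparationError
        If the fitted linear predictor diverges (separation) or the
        information matrix is singular.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    beta = np.zeros(p)
    # warm start on the intercept-like column if X[:,0] is constant 1
    ybar = y.mean()
    if 0.0 < ybar < 1.0 and np.all(X[:, 0] == 1.0):
        beta[0] = np.log(ybar / (1.0 - ybar))
    elif ybar in (0.0, 1.0):
        raise SeparationError("response is constant")
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if np.max(np.abs(eta)) > 40.0:
            raise SeparationError("diverging linear predictor")
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_prev) < tol and np.max(np.abs(step)) < 1e-8:
            break
        ll_prev = ll
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("singular information matrix at optimum") from exc
    converged = abs(ll - ll_prev) < max(tol, 1e-8 * (1 + abs(ll)))
    return LogitFit(beta=beta, cov=cov, mu=mu, converged=converged, n_iter=it)


def wald_chi2(fit: LogitFit, index: int) -> float:
    """1-df Wald chi-square for one coefficient of a fitted model."""
    se2 = fit.cov[index, index]
    if se2 <= 0:
        raise SeparationError("non-positive variance estimate")
    return float(fit.beta[index] ** 2 / se2)


def score_test_components(G: np.ndarray, y: np.ndarray, X0: np.ndarray,
                          mu0: np.ndarray):
    """Score vector and its null covariance for markers G given a null fit.

    Given the null model fit (design ``X0``, fitted means ``mu0``) the score
    for adding marker columns ``G`` is ``U = G'(y - mu0)`` with null covariance
    ``V = G'WG - G'WX0 (X0'WX0)^-1 X0'WG``, W = diag(mu0(1-mu0)). These are
    the building blocks of both the single-marker score test and the kernel
    (variance-component) test.
    """
    G = np.asarray(G, dtype=np.float64)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(y, dtype=np.float64)
    w = mu0 * (1.0 - mu0)
    U = G.T @ (y - mu0)
    WG = G * w[:, None]
    V = G.T @ WG
    if X0 is not None and X0.size:
        WX = X0 * w[:, None]
        XtWX = X0.T @ WX
        B = np.linalg.solve(XtWX, WX.T @ G)
        V = V - (WX.T @ G).T @ B
    return U, V
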
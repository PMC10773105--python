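"""Logistic regression with Firth fallback.

Rare-CNV case/control regressions frequently run into (quasi-)separation:
all carriers may be cases, leaving the maximum-likelihood estimate
divergent. The scan therefore first attempts a plain Newton-Raphson ML fit
and falls back to Firth's Jeffreys-prior penalized likelihood — which always
yields finite estimates — when the ML fit fails.

Fallback triggers: ML non-convergence, any |beta| > 10 on the fitted scale,
or (at the caller's discretion) an empty cell in the genotype x outcome
table, which is a deterministic witness of separation risk.

Inference is Wald throughout: p = 2 * Phi(-|beta/se|), 95% CI on the odds
ratio as exp(beta -/+ 1.96 se), matching the reporting convention of
standard GWAS tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.linalg import LinAlgWarning
from scipy.special import expit
from scipy.stats import norm

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100
BETA_DIVERGENCE = 10.0


@dataclass
class LogisticFit:
    """Per-column estimates from an (optionally penalized) logistic fit."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    firth_used: bool
    converged: bool
    loglik: float
    n_iter: int
    columns: list[int] = field(default_factory=list)  # surviving design columns
    dropped: list[int] = field(default_factory=list)  # collinear columns removed

    def wald_ci(self, j: int, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        return (self.beta[j] - z * self.se[j], self.beta[j] + z * self.se[j])


def _loglik(y, X, beta):
    eta = X @ beta
    # log(sigmoid) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _drop_collinear(X: np.ndarray) -> tuple[np.ndarray, list[int], list[int]]:
    """QR with column pivoting; keeps a maximal independent column subset."""
    n, k = X.shape
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    kept = sorted(piv[:rank].tolist())
    dropped = sorted(set(range(k)) - set(kept))
    return X[:, kept], kept, dropped


def _quiet_linalg(fn):
    """Silence ill-conditioning warnings: a diverging ML fit is an expected
    intermediate state handled by the Firth fallback, not a user-facing
    problem."""

    def wrapper(*args, **kwargs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LinAlgWarning)
            return fn(*args, **kwargs)

    wrapper.__name__ = fn.__name__
    wrapper.__doc__ = fn.__doc__
    return wrapper


@_quiet_linalg
def fit_ml(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LogisticFit:
    """Newton-Raphson maximum likelihood with step halving."""
    n, k = X.shape
    beta = np.zeros(k)
    ll = _loglik(y, X, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = p * (1.0 - p)
        info = X.T @ (X * W[:, None])
        score = X.T @ (y - p)
        try:
            delta = linalg.solve(info, score, assume_a="pos")
        except linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            ll_new = _loglik(y, X, cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll = beta + step * delta, _loglik(y, X, beta + step * delta)
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    W = p * (1.0 - p)
    info = X.T @ (X * W[:, None])
    try:
        cov = linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except linalg.LinAlgError:
        se = np.full(k, np.inf)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    pvals = np.where(np.isfinite(z), pvals, 1.0)
    return LogisticFit(beta, se, pvals, False, converged, ll, it)


def firth_penalized_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    """log L(beta) + 0.5 * log |X' W X| (Jeffreys-prior penalty)."""
    p = expit(X @ beta)
    W = p * (1.0 - p)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _loglik(y, X, beta) + 0.5 * logdet


@_quiet_linalg
def fit_firth(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LogisticFit:
    """Firth penalized-likelihood fit via modified-score Newton iterations."""
    n, k = X.shape
    beta = np.zeros(k)
    pll = firth_penalized_loglik(y, X, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = p * (1.0 - p)
        XW = X * W[:, None]
        info = X.T @ XW
        try:
            info_inv = linalg.inv(info)
        except linalg.LinAlgError:
            break
        # leverages of the weighted design: h_i = w_i x_i' (X'WX)^-1 x_i
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        delta = info_inv @ score
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            pll_new = firth_penalized_loglik(y, X, cand)
            if pll_new >= pll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        pll = firth_penalized_loglik(y, X, beta)
        if np.max(np.abs(step * delta)) < tol or np.max(np.abs(score)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    W = p * (1.0 - p)
    info = X.T @ (X * W[:, None])
    cov = linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    return LogisticFit(beta, se, pvals, True, converged, pll, it)


def firth_logistic(
    y: np.ndarray,
    X: np.ndarray,
    force_firth: bool = False,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LogisticFit:
    """ML logistic fit with automatic Firth fallback.

    ``X`` must include an intercept column. Collinear columns are dropped
    (QR pivoting) and recorded in ``fit.dropped``; estimates in the returned
    fit are re-expanded to the original column order with beta 0, se inf,
    and p 1 for dropped columns. ``force_firth`` skips the ML attempt (used
    when the caller detected an empty genotype x outcome cell).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != len(y):
        raise ValueError("incompatible y/X shapes")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("y must be binary 0/1")
    if len(uniq) < 2:
        raise ValueError("outcome is constant: all samples in one class")

    Xr, kept, dropped = _drop_collinear(X)
    if not force_firth:
        fit = fit_ml(y, Xr, tol=tol, max_iter=max_iter)
        if not fit.converged or np.any(np.abs(fit.beta) > BETA_DIVERGENCE):
            fit = fit_firth(y, Xr, tol=tol, max_iter=max_iter)
    else:
        fit = fit_firth(y, Xr, tol=tol, max_iter=max_iter)

    k = X.shape[1]
    beta = np.zeros(k)
    se = np.full(k, np.inf)
    p = np.ones(k)
    beta[kept], se[kept], p[kept] = fit.beta, fit.se, fit.p
    return LogisticFit(
        beta, se, p, fit.firth_used, fit.converged, fit.loglik, fit.n_iter,
        columns=kept, dropped=dropped,
    )
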
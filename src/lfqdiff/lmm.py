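"""Linear mixed model with a single random intercept, by profiled REML/ML.

This is the XIC quantification model: for one protein, log10 peptide
intensities are

    y = X beta + Z theta + eps,   theta_s ~ N(0, sigma_theta^2),
                                  eps ~ N(0, sigma_eps^2),

where Z groups observations by sample, so theta is the technical
variation shared by all of a protein's peptides within one LC-MS run.

With W = I + lambda Z Z' and lambda = sigma_theta^2 / sigma_eps^2, both
likelihoods profile down to a one-dimensional search over lambda. For a
group of size n_s the whitening transform is

    y_tilde = y - c_s * ybar_s,   c_s = 1 - 1 / sqrt(1 + n_s * lambda),

(the same transform column-wise for X), after which GLS is ordinary least
squares. The criteria minimized are

    ML:    N log(2 pi s2) + N + sum_s log(1 + n_s lambda),
           s2 = RSS / N
    REML:  (N-p) log(2 pi s2) + (N-p) + sum_s log(1 + n_s lambda)
           + log det(X~' X~),          s2 = RSS / (N-p)

The boundary estimate sigma_theta^2 = 0 (lambda = 0) is valid and is
returned when it minimizes the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["LMMFit", "fit_random_intercept"]

_LOG_LAMBDA_BOUNDS = (-14.0, 10.0)


@dataclass
class LMMFit:
    beta: np.ndarray
    sigma_eps2: float
    sigma_theta2: float
    loglik: float  # restricted log-likelihood if reml else log-likelihood
    reml: bool
    converged: bool
    rank: int
    nobs: int


def _criterion(
    log_lambda: float,
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    group_sizes: np.ndarray,
    reml: bool,
) -> tuple[float, np.ndarray, float]:
    """-2 * profiled log-likelihood at lambda = exp(log_lambda).

    Returns (criterion, beta, rss). lambda = 0 is passed as -inf.
    """
    n, p = X.shape
    lam = np.exp(log_lambda) if np.isfinite(log_lambda) else 0.0
    if lam > 0:
        c = 1.0 - 1.0 / np.sqrt(1.0 + group_sizes * lam)
        ybar = np.bincount(group_idx, weights=y) / group_sizes
        yt = y - c[group_idx] * ybar[group_idx]
        Xbar = np.empty((len(group_sizes), p))
        for j in range(p):
            Xbar[:, j] = np.bincount(group_idx, weights=X[:, j]) / group_sizes
        Xt = X - (c[:, None] * Xbar)[group_idx]
        logdet_w = float(np.sum(np.log1p(group_sizes * lam)))
    else:
        yt, Xt, logdet_w = y, X, 0.0
    beta, _res, rank, _sv = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    if reml:
        dof = n - rank
        s2 = max(rss / dof, 1e-300)
        sign, logdet_xtx = np.linalg.slogdet(Xt.T @ Xt)
        crit = dof * (np.log(2 * np.pi * s2) + 1.0) + logdet_w + logdet_xtx
    else:
        s2 = max(rss / n, 1e-300)
        crit = n * (np.log(2 * np.pi * s2) + 1.0) + logdet_w
    return crit, beta, rss


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
) -> LMMFit:
    """Fit the random-intercept LMM by profiling the variance ratio.

    ``groups`` is an array of hashable group labels (one per row). The
    optimum over log(lambda) is located with bounded scalar minimization
    and compared against the lambda = 0 boundary.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _, group_idx = np.unique(groups, return_inverse=True)
    group_sizes = np.bincount(group_idx).astype(float)
    n = len(y)

    # degenerate data: no residual variation at all
    if np.ptp(y) < 1e-12:
        beta = np.zeros(X.shape[1])
        # intercept-only solution reproducing the constant
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        return LMMFit(beta0, 0.0, 0.0, np.inf, reml, True, np.linalg.matrix_rank(X), n)

    def f(u: float) -> float:
        return _criterion(u, y, X, group_idx, group_sizes, reml)[0]

    res = minimize_scalar(
        f, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    crit0, _, _ = _criterion(-np.inf, y, X, group_idx, group_sizes, reml)
    if crit0 <= res.fun:
        best_u, best_crit = -np.inf, crit0
    else:
        best_u, best_crit = float(res.x), float(res.fun)
    # an optimum pinned at the lower bound is the boundary case lambda = 0
    if np.isfinite(best_u) and best_u <= _LOG_LAMBDA_BOUNDS[0] + 1e-6:
        best_u, best_crit = -np.inf, crit0

    _, beta, rss = _criterion(best_u, y, X, group_idx, group_sizes, reml)
    rank = int(np.linalg.matrix_rank(X))
    dof = n - rank if reml else n
    sigma_eps2 = rss / dof
    lam = np.exp(best_u) if np.isfinite(best_u) else 0.0
    sigma_theta2 = lam * sigma_eps2
    return LMMFit(
        beta=beta,
        sigma_eps2=float(sigma_eps2),
        sigma_theta2=float(sigma_theta2),
        loglik=-0.5 * best_crit,
        reml=reml,
        converged=bool(res.success or crit0 <= res.fun),
        rank=rank,
        nobs=n,
    )
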
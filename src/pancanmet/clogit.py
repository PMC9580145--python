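"""Unpenalized conditional logistic regression for 1:1 matched pairs.

Uses the standard reduction of the 1:1 conditional likelihood to an
intercept-free logistic likelihood on case-minus-control difference rows
with all responses equal to one:

    l(beta) = sum_i log sigma(d_i' beta)

maximised by Newton-Raphson with step halving.  Also provides the natural
cubic spline basis used by the linearity checks (linear leading column, so
the linear model is exactly nested in the spline model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ClogitFit:
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    estimable: np.ndarray  # per-term flag (False under separation/aliasing)
    n_pairs: int

    def ci(self, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        z = stats.norm.ppf(1 - alpha / 2)
        return self.params - z * self.se, self.params + z * self.se

    def wald_pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.se
        return 2 * stats.norm.sf(np.abs(z))


def null_loglik(n_pairs: int) -> float:
    """Conditional log-likelihood of the empty model (coin-flip per pair)."""
    return n_pairs * np.log(0.5)


def fit_clogit(
    D: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    grad_tol: float = 1e-9,
    max_abs_coef: float = 30.0,
) -> ClogitFit:
    """Maximum conditional likelihood on a pair-difference design.

    Separation or aliasing is reported through the per-term ``estimable``
    flags (diverging estimate or unbounded Wald SE) rather than raised.
    """
    D = np.asarray(D, dtype=float)
    n, p = D.shape
    if p == 0:
        return ClogitFit(
            np.empty(0), np.empty(0), np.empty((0, 0)),
            null_loglik(n), True, np.empty(0, dtype=bool), n,
        )
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    ll = _loglik(D, beta)
    converged = False
    for _ in range(max_iter):
        eta = D @ beta
        pr = 1.0 / (1.0 + np.exp(-eta))
        g = D.T @ (1.0 - pr)
        W = pr * (1.0 - pr)
        H = (D * W[:, None]).T @ D
        if np.max(np.abs(g)) < grad_tol * max(1.0, n / 100):
            converged = True
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving keeps the likelihood non-decreasing
        t = 1.0
        for _half in range(40):
            cand = beta + t * step
            ll_new = _loglik(D, cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta, ll = cand, ll_new
        if np.max(np.abs(beta)) > max_abs_coef:
            break  # diverging: separation
    eta = D @ beta
    pr = 1.0 / (1.0 + np.exp(-eta))
    W = pr * (1.0 - pr)
    H = (D * W[:, None]).T @ D
    estimable = np.abs(beta) <= max_abs_coef
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        estimable &= np.isfinite(se) & (se < 1e3)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
        estimable[:] = False
    return ClogitFit(beta, se, cov, float(ll), converged, estimable, n)


def _loglik(D: np.ndarray, beta: np.ndarray) -> float:
    return float(-np.sum(np.logaddexp(0.0, -(D @ beta))))


def lrt_pvalue(ll_full: float, ll_reduced: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic and p-value for nested fits."""
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return stat, p


def natural_spline_basis(
    x: np.ndarray,
    knot_quantiles: tuple = (0.25, 0.5, 0.75),
    boundary_quantiles: tuple = (0.05, 0.95),
    knots: np.ndarray | None = None,
) -> np.ndarray:
    """Natural cubic spline basis with a linear leading column.

    With interior knots at the stated quantiles and boundary knots treated
    as outer knots, the basis is ``[x, N_1(x), ..., N_{K-2}(x)]`` in the
    truncated-power natural-spline construction (linear beyond the
    boundary), giving 4 regression degrees of freedom for the default
    3 + 2 knots.  The leading column is exactly ``x``, so a linear model
    is nested.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        qs = sorted(set(boundary_quantiles) | set(knot_quantiles))
        knots = np.quantile(x, qs)
    knots = np.unique(np.asarray(knots, dtype=float))
    K = len(knots)
    if K < 3:
        raise ValueError(
            f"insufficient distinct knot values ({K}); need at least 3 distinct quantiles"
        )

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dK2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK2)
    return np.column_stack(cols)
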
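"""Statistical primitives used across the pipeline.

The Pearson p-value uses the exact t reference distribution with n-2
degrees of freedom; the hypergeometric upper tail is accumulated in log
space; the false-discovery adjustment is the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "pearson_with_p",
    "pearson_matrix_with_p",
    "hypergeometric_upper",
    "benjamini_hochberg",
]


class ZeroVarianceError(ValueError):
    """Correlation is undefined because one input is constant."""


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value.

    The p-value comes from transforming r to t = r * sqrt((n-2) / (1-r^2))
    and referring to a Student-t distribution with n-2 degrees of freedom.
    Perfect correlations (|r| = 1) get p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("correlation undefined: zero variance input")
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def pearson_matrix_with_p(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided p for paired rows of X and Y.

    X and Y have shape (n_pairs, n_samples); row i of X is correlated with
    row i of Y.  Rows with zero variance yield NaN r and p = 1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("X and Y must share shape (n_pairs, n_samples)")
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc * Xc).sum(axis=1))
    sy = np.sqrt((Yc * Yc).sum(axis=1))
    denom = sx * sy
    ok = denom > 0
    r = np.full(X.shape[0], np.nan)
    r[ok] = np.clip((Xc * Yc).sum(axis=1)[ok] / denom[ok], -1.0, 1.0)
    p = np.ones(X.shape[0])
    finite = ok & (np.abs(r) < 1.0)
    t = r[finite] * np.sqrt((n - 2) / (1.0 - r[finite] ** 2))
    p[finite] = np.minimum(2.0 * sps.t.sf(np.abs(t), df=n - 2), 1.0)
    p[ok & (np.abs(r) == 1.0)] = 0.0
    return r, p


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of marked items, n the draw
    size and k the observed overlap.  The tail is accumulated from log
    probabilities to stay accurate for extreme parameters.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError(f"K and n must not exceed N (K={K}, n={n}, N={N})")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    lo = max(0, n + K - N)
    if support.size == 0 or support[-1] < lo:
        return 0.0
    logpmf = sps.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logpmf[np.isfinite(logpmf)]))))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns q_i = min_{j: p_(j) >= p_(i)} (m * p_(j) / j) capped at 1, in
    the input order.  Ties are handled by the stable sort, which leaves
    equal p-values with equal adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
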
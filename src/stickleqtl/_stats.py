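"""Shared Gaussian-likelihood helpers for the linear-model tests.

All chromosome tests in this package compare nested Gaussian linear models
fitted by maximum likelihood (MLE variance), so 2*delta-loglik reduces to
n*log(RSS_reduced / RSS_full).
"""
from __future__ import annotations

import math

import numpy as np


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood given the residual sum of squares."""
    if n <= 0:
        raise ValueError("n must be positive")
    # sigma2_hat = rss / n; degenerate rss=0 would give +inf, guard with tiny
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def group_mean_rss(y: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """RSS of the cell-means model (one mean per label) and its class count."""
    y = np.asarray(y, dtype=float)
    rss = 0.0
    uniq = np.unique(labels)
    for lab in uniq:
        v = y[labels == lab]
        rss += float(np.sum((v - v.mean()) ** 2))
    return rss, len(uniq)


def ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    """RSS of an ordinary least-squares fit y ~ X."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def lrt_from_rss(rss_full: float, rss_reduced: float, n: int, df: int):
    """2*delta-loglik of a nested Gaussian comparison, clamped at zero.

    Returns (statistic, p_value). The clamp only absorbs numerical jitter;
    for genuinely nested fits RSS_reduced >= RSS_full.
    """
    from scipy import stats

    rss_full = max(rss_full, 1e-300)
    rss_reduced = max(rss_reduced, 1e-300)
    stat = n * math.log(rss_reduced / rss_full)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return stat, p
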
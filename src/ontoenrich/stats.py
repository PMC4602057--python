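"""Hypergeometric enrichment/depletion p-values and step-up q-values.

The sampling model: a query of n genes drawn without replacement from a
universe of N annotated genes, of which K carry a given term (directly
or through descendants). The number of term-bearing genes in the query,
X, is Hypergeometric(N, K, n). Enrichment asks for P(X >= k), depletion
for P(X <= k).

Tail probabilities are computed by summing log-space pmf terms from
whichever tail is shorter — never by a 1 - cdf subtraction on the small
tail — so headline p-values around 1e-300 keep full relative accuracy
for universes up to ~1e6 genes.

Multiple testing is controlled with the step-up positive-FDR estimator
over the ordered p-values: q_(i) = min_{j >= i} pi0 * m * p_(j) / j,
with pi0 = 1 by default (equivalently the Benjamini-Hochberg adjusted
p-value). An optional pi0 estimate (lambda = 0.5 census) is available.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import StatsDomainError


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if N < 0:
        raise StatsDomainError(f"N >= 0 violated (N={N})")
    if not 0 <= K <= N:
        raise StatsDomainError(f"0 <= K <= N violated (K={K}, N={N})")
    if not 0 <= n <= N:
        raise StatsDomainError(f"0 <= n <= N violated (n={n}, N={N})")
    lo, hi = max(0, n + K - N), min(n, K)
    if not lo <= k <= hi:
        raise StatsDomainError(
            f"max(0, n+K-N) <= k <= min(n, K) violated (k={k}, n={n}, K={K}, N={N})"
        )


def _log_choose(a, b):
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def log_pmf(k, n: int, K: int, N: int):
    """Log of the hypergeometric pmf; ``k`` may be an array inside the support."""
    k = np.asarray(k, dtype=float)
    return _log_choose(K, k) + _log_choose(N - K, n - k) - _log_choose(N, n)


def pmf(k: int, n: int, K: int, N: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n)."""
    _check_counts(k, n, K, N)
    return float(np.exp(log_pmf(k, n, K, N)))


def _tail(k: int, n: int, K: int, N: int, upper: bool) -> float:
    lo, hi = max(0, n + K - N), min(n, K)
    if upper:
        if k <= lo:
            return 1.0
        own = np.arange(k, hi + 1)
        other = np.arange(lo, k)
    else:
        if k >= hi:
            return 1.0
        own = np.arange(lo, k + 1)
        other = np.arange(k + 1, hi + 1)
    if len(own) <= len(other):
        p = float(np.exp(logsumexp(log_pmf(own, n, K, N))))
    else:
        p = 1.0 - float(np.exp(logsumexp(log_pmf(other, n, K, N))))
    return min(1.0, max(0.0, p))


def enrichment_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail p-value P(X >= k): at least k query genes bear the term.

    Returns exactly 1.0 when k is at (or below) the lower support bound
    max(0, n+K-N).
    """
    _check_counts(k, n, K, N)
    return _tail(k, n, K, N, upper=True)


def depletion_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Lower-tail p-value P(X <= k): at most k query genes bear the term.

    Returns exactly 1.0 when k equals min(n, K).
    """
    _check_counts(k, n, K, N)
    return _tail(k, n, K, N, upper=False)


def estimate_pi0(pvalues: Sequence[float], lam: float = 0.5) -> float:
    """Census estimate of the null proportion: #{p > lam} / (m * (1 - lam))."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return 1.0
    pi0 = float(np.mean(p > lam) / (1.0 - lam))
    return min(1.0, max(pi0, 1.0 / p.size))


def qvalues(
    pvalues: Sequence[float],
    m: Optional[int] = None,
    pi0: float = 1.0,
) -> np.ndarray:
    """Step-up q-values over the ordered p-values, in input order.

    ``m`` is the number of tests (may exceed ``len(pvalues)`` when
    untestable hypotheses are counted); ``pi0`` scales the estimator
    (1.0 reproduces Benjamini-Hochberg adjusted p-values). The q-value
    in sorted row i estimates the false-positive rate incurred by
    calling rows 0..i significant.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0.0 or np.max(p) > 1.0):
        raise StatsDomainError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise StatsDomainError(f"m ({m}) smaller than number of p-values ({p.size})")
    if p.size == 0:
        return np.empty(0, dtype=float)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1, dtype=float)
    scaled = pi0 * m * p[order] / ranks
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
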
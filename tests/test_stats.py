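"""Hypergeometric tails against exhaustive enumeration, q-values against
the direct step-up oracle and statsmodels."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoenrich.errors import StatsDomainError
from ontoenrich.stats import (
    depletion_pvalue,
    enrichment_pvalue,
    estimate_pi0,
    pmf,
    qvalues,
)


def enumerate_tail_counts(N: int, K: int, n: int) -> dict[int, int]:
    """Count draws by number of successes over all C(N,n) equally likely draws."""
    successes = set(range(K))
    counts: dict[int, int] = {}
    for draw in itertools.combinations(range(N), n):
        k = sum(1 for x in draw if x in successes)
        counts[k] = counts.get(k, 0) + 1
    return counts


def test_enrichment_matches_spec_enumeration_values():
    # 66 of the C(10,5)=252 draws contain >= 3 of the 4 successes
    assert enrichment_pvalue(3, 5, 4, 10) == pytest.approx(66 / 252, abs=1e-12)
    assert enrichment_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252, abs=1e-12)
    assert enrichment_pvalue(0, 5, 3, 10) == 1.0


def test_depletion_matches_spec_enumeration_values():
    assert depletion_pvalue(5, 5, 5, 10) == 1.0
    # only C(6,5)=6 draws avoid all 4 successes
    assert depletion_pvalue(0, 5, 4, 10) == pytest.approx(6 / 252, abs=1e-12)


@pytest.mark.parametrize("N", [1, 4, 7, 9])
def test_tails_equal_enumeration_small_grid(N):
    for K in range(N + 1):
        for n in range(N + 1):
            counts = enumerate_tail_counts(N, K, n)
            total = math.comb(N, n)
            lo, hi = max(0, n + K - N), min(n, K)
            for k in range(lo, hi + 1):
                upper = sum(c for kk, c in counts.items() if kk >= k) / total
                lower = sum(c for kk, c in counts.items() if kk <= k) / total
                assert enrichment_pvalue(k, n, K, N) == pytest.approx(upper, abs=1e-12)
                assert depletion_pvalue(k, n, K, N) == pytest.approx(lower, abs=1e-12)
                assert (
                    enrichment_pvalue(k, n, K, N)
                    + depletion_pvalue(k, n, K, N)
                    - pmf(k, n, K, N)
                ) == pytest.approx(1.0, abs=1e-12)


def test_boundary_values_exact():
    assert enrichment_pvalue(0, 5, 3, 10) == 1.0
    assert enrichment_pvalue(2, 5, 7, 10) == 1.0  # k at the lower support bound
    assert depletion_pvalue(3, 3, 8, 10) == 1.0  # k == min(n, K)


def test_extreme_tail_is_accurate_not_cancelled():
    # P(X >= 50) with n=K=50, N=1e6: product of (50-i)/(1e6-i), ~1e-215
    expected = math.exp(
        sum(math.log((50 - i) / (1_000_000 - i)) for i in range(50))
    )
    p = enrichment_pvalue(50, 50, 50, 1_000_000)
    assert p == pytest.approx(expected, rel=1e-9)
    assert p > 0.0


def test_scipy_cross_check():
    from scipy.stats import hypergeom

    for (k, n, K, N) in [(3, 40, 60, 1000), (12, 40, 60, 1000), (0, 40, 600, 1000)]:
        assert enrichment_pvalue(k, n, K, N) == pytest.approx(
            float(hypergeom.sf(k - 1, N, K, n)), rel=1e-9
        )
        assert depletion_pvalue(k, n, K, N) == pytest.approx(
            float(hypergeom.cdf(k, N, K, n)), rel=1e-9
        )


def test_monotone_nonincreasing_in_k():
    n, K, N = 20, 30, 100
    ps = [enrichment_pvalue(k, n, K, N) for k in range(0, min(n, K) + 1)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


@pytest.mark.parametrize(
    "kwargs,msg",
    [
        (dict(k=3, n=5, K=11, N=10), "K <= N"),
        (dict(k=3, n=11, K=5, N=10), "n <= N"),
        (dict(k=6, n=5, K=5, N=10), "k <= min"),
        (dict(k=-1, n=5, K=5, N=10), "k <= min"),
    ],
)
def test_domain_errors_name_violated_inequality(kwargs, msg):
    with pytest.raises(StatsDomainError, match=msg):
        enrichment_pvalue(**kwargs)


def stepup_oracle(ps, m, pi0=1.0):
    order = sorted(range(len(ps)), key=lambda i: ps[i])
    q = [None] * len(ps)
    for rank_i, i in enumerate(order, start=1):
        q[i] = min(
            min(pi0 * m * ps[j] / (r) for r, j in enumerate(order, start=1) if r >= rank_i),
            1.0,
        )
    return q


def test_qvalue_spec_examples():
    assert list(qvalues([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]
    assert np.allclose(qvalues([0.01, 0.02, 0.5], m=3), [0.03, 0.03, 0.5])
    assert list(qvalues([0.2], m=1)) == [0.2]


def test_qvalues_with_m_exceeding_list_length():
    # untested hypotheses inflate m, hence q
    assert np.allclose(qvalues([0.01], m=10), [0.1])
    with pytest.raises(StatsDomainError):
        qvalues([0.1, 0.2], m=1)


def test_qvalues_match_statsmodels_bh():
    sm = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(7)
    for _ in range(20):
        ps = rng.uniform(size=rng.integers(1, 60))
        _, bh, _, _ = sm.multipletests(ps, method="fdr_bh")
        assert np.allclose(qvalues(ps), bh, atol=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
    st.integers(min_value=0, max_value=50),
)
def test_qvalue_contract_properties(ps, extra_m):
    m = len(ps) + extra_m
    q = qvalues(ps, m=m)
    assert np.all(q <= 1.0 + 1e-15)
    assert np.all(q >= np.minimum(np.asarray(ps), 1.0) - 1e-15)  # q >= p (m >= rank)
    order = np.argsort(ps, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-15)  # monotone along sorted p
    # exact agreement with the direct step-up oracle
    assert np.allclose(q, stepup_oracle(ps, m), atol=1e-12)
    # permutation equivariance
    perm = np.arange(len(ps))[::-1]
    assert np.allclose(qvalues(list(np.asarray(ps)[perm]), m=m), q[perm], atol=1e-12)


def test_estimate_pi0_census():
    # 40 of 100 p-values above 0.5 -> pi0 = 0.8
    ps = [0.25] * 60 + [0.75] * 40
    assert estimate_pi0(ps) == pytest.approx(0.8)
    assert estimate_pi0([0.9] * 10) == 1.0  # clipped at 1
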
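"""Rank-test and multiple-testing primitives.

These back both the bead-level detection call (one-sided Mann-Whitney against
negative-control beads) and the per-probe two-sample Wilcoxon used for
differential methylation. The exact small-sample branch matters: with five
samples per group the test has only C(10,5)=252 attainable statistics, so the
normal approximation is a poor substitute.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = ["bh_adjust", "mannwhitney_p", "wilcoxon_rank_sum"]

#: largest number of group assignments enumerated per probe when ties force a
#: probe-specific exact null; beyond this the tie-corrected normal
#: approximation is used.
MAX_EXACT_COMBINATIONS = 500_000


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Sorts ascending, takes ``adj_i = min_{j>=i} (m * p_j / j)`` capped at 1,
    and returns the adjusted values in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("bh_adjust expects a 1-d collection of P-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("P-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    np.minimum(adjusted, 1.0, out=adjusted)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mannwhitney_p(
    x,
    y,
    alternative: str = "greater",
    method: str = "auto",
) -> float:
    """Mann-Whitney U P-value for two scalar samples.

    ``method='auto'`` uses the exact permutation distribution when the input
    is tie-free and small enough to enumerate, and the tie-corrected normal
    approximation (with continuity correction) otherwise.  Under the
    mid-rank convention two identical samples give P close to 0.5 one-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully tied: U sits at its null mean under mid-ranks
        return 1.0 if alternative == "two-sided" else 0.5
    if method == "auto":
        tie_free = not _has_ties(pooled)
        if tie_free and comb(x.size + y.size, x.size) <= MAX_EXACT_COMBINATIONS:
            method = "exact"
        else:
            method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


@lru_cache(maxsize=32)
def _ranksum_null_counts(n_a: int, n_total: int) -> tuple[np.ndarray, int]:
    """Exact null distribution of the rank-sum of ``n_a`` untied ranks.

    Returns ``(counts, min_sum)`` where ``counts[s - min_sum]`` is the number
    of size-``n_a`` subsets of {1..n_total} with sum ``s``.
    """
    min_sum = n_a * (n_a + 1) // 2
    max_sum = n_a * (2 * n_total - n_a + 1) // 2
    # dp[k][s]: subsets of size k summing to s
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for value in range(1, n_total + 1):
        for k in range(min(value, n_a), 0, -1):
            dp[k, value:] += dp[k - 1, : max_sum + 1 - value]
    return dp[n_a, min_sum:], min_sum


@lru_cache(maxsize=8)
def _combination_index(n_total: int, n_a: int) -> np.ndarray:
    return np.array(
        list(itertools.combinations(range(n_total), n_a)), dtype=np.intp
    )


def _twosided_from_tails(p_low: np.ndarray, p_high: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, 2.0 * np.minimum(p_low, p_high))


def _exact_p_from_universal(w_obs: np.ndarray, n_a: int, n_total: int) -> np.ndarray:
    counts, min_sum = _ranksum_null_counts(n_a, n_total)
    total = counts.sum()
    cdf = np.cumsum(counts)
    idx = np.round(w_obs - min_sum).astype(np.intp)
    idx = np.clip(idx, 0, counts.size - 1)
    p_low = cdf[idx] / total
    sf = np.cumsum(counts[::-1])[::-1]
    p_high = sf[idx] / total
    return _twosided_from_tails(p_low, p_high)


def _exact_p_enumerated(ranks_row: np.ndarray, n_a: int) -> float:
    """Probe-specific exact two-sided P, enumerating all group assignments.

    Needed when mid-ranks (ties) make the null distribution probe-specific.
    """
    n_total = ranks_row.size
    combos = _combination_index(n_total, n_a)
    w_perm = ranks_row[combos].sum(axis=1)
    w_obs = ranks_row[:n_a].sum()
    eps = 1e-9
    p_low = np.mean(w_perm <= w_obs + eps)
    p_high = np.mean(w_perm >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided two-sample Wilcoxon (Mann-Whitney) P-values, per row.

    ``a`` (probes x n_a) and ``b`` (probes x n_b) hold the per-sample values
    of both groups.  For group sizes up to 10 per side the exact permutation
    null is used (a shared distribution for tie-free rows; a per-row
    enumeration when mid-ranks appear); larger designs fall back to the
    tie-corrected normal approximation.  Rows that are constant across both
    groups get P = 1.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise InputError("group matrices must have the same number of rows")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise InputError("need at least 2 samples per group")
    n_total = n_a + n_b
    pooled = np.concatenate([a, b], axis=1)

    if n_a > 10 or n_b > 10:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", axis=-1
        )
        p = np.asarray(res.pvalue, dtype=float)
        constant = np.all(pooled == pooled[:, :1], axis=1)
        p[constant] = 1.0
        return p

    ranks = sps.rankdata(pooled, axis=1)
    w_obs = ranks[:, :n_a].sum(axis=1)
    # mid-ranks are integers (or all-equal) iff the row is tie-free
    tied = np.array([_has_ties(row) for row in pooled])
    p = np.empty(pooled.shape[0], dtype=float)
    if np.any(~tied):
        p[~tied] = _exact_p_from_universal(w_obs[~tied], n_a, n_total)
    if np.any(tied):
        if comb(n_total, n_a) <= MAX_EXACT_COMBINATIONS:
            for i in np.flatnonzero(tied):
                p[i] = _exact_p_enumerated(ranks[i], n_a)
        else:  # pragma: no cover - unreachable for n<=10 per side
            res = sps.mannwhitneyu(
                a[tied], b[tied], alternative="two-sided", method="asymptotic",
                axis=-1,
            )
            p[tied] = res.pvalue
    constant = np.all(pooled == pooled[:, :1], axis=1)
    p[constant] = 1.0
    return p
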
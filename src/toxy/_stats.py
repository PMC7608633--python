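"""Shared statistical primitives.

The two-sample rank-sum test is used throughout (sex comparisons of TE
abundance, window-class enrichment contrasts, insertion residual
comparisons).  Small groups are tested by exact enumeration over all label
assignments, which handles ties correctly; larger groups fall back to the
normal approximation with tie correction (scipy's asymptotic Mann-Whitney).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

# exact enumeration is used whenever the number of assignments is below this
_EXACT_LIMIT = 20_000


def rank_sum_test(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided two-sample rank-sum (Mann-Whitney/Wilcoxon) test.

    Returns ``(rank_sum_of_x, p_value)`` where the statistic is the sum of
    pooled midranks of ``x``.  ``method`` is ``"auto"`` (exact when
    C(n1+n2, n1) <= 20000, asymptotic otherwise), ``"exact"`` or
    ``"asymptotic"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())

    if method == "auto":
        method = "exact" if comb(n1 + n2, n1) <= _EXACT_LIMIT else "asymptotic"

    if method == "exact":
        mu = n1 * (n1 + n2 + 1) / 2.0
        obs = abs(w - mu)
        total = 0
        hits = 0
        # enumerate all assignments of n1 labels to the pooled ranks
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
                hits += 1
        return w, hits / total

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided p; r=0, p=1 for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
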
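"""Two-sample rank-sum (Mann-Whitney U) test with a small-sample exact null.

For small pooled sizes the two-sided p-value is computed by full enumeration
of group assignments over the pooled midranks, which stays valid under ties;
larger samples use the normal approximation with tie and continuity
correction (scipy's asymptotic method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from scipy.stats import mannwhitneyu, rankdata

__all__ = ["RankSumResult", "rank_sum_test", "EXACT_LIMIT"]

#: Largest pooled sample size for which the exact null is enumerated.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U result; ``statistic`` is U for the first group."""

    statistic: float
    n_private: int
    n_other: int
    p_two_sided: float
    method: str  # "exact" | "normal-approx-with-tie-correction"


def _u_statistic(ranks: Sequence[float], idx: Sequence[int], n1: int) -> float:
    return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> RankSumResult:
    """Two-sided Mann-Whitney U comparing ``x`` against ``y``.

    Exact enumeration of all C(n1+n2, n1) assignments when
    ``n1 + n2 <= exact_limit`` (correct under ties); otherwise the normal
    approximation with tie correction and continuity correction.  Two-sided
    exact p is the null probability of a U at least as far from n1*n2/2 as
    observed.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    if n1 == 0:
        raise ValueError("first (private) group is empty")
    if n2 == 0:
        raise ValueError("second (other) group is empty")

    if n1 + n2 <= exact_limit:
        pooled = x + y
        ranks = rankdata(pooled)
        mu = n1 * n2 / 2.0
        u_obs = _u_statistic(ranks, range(n1), n1)
        dev = abs(u_obs - mu)
        hits = 0
        total = math.comb(n1 + n2, n1)
        for idx in combinations(range(n1 + n2), n1):
            if abs(_u_statistic(ranks, idx, n1) - mu) >= dev - 1e-9:
                hits += 1
        return RankSumResult(
            statistic=float(u_obs),
            n_private=n1,
            n_other=n2,
            p_two_sided=hits / total,
            method="exact",
        )

    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return RankSumResult(
        statistic=float(res.statistic),
        n_private=n1,
        n_other=n2,
        p_two_sided=min(1.0, float(res.pvalue)),
        method="normal-approx-with-tie-correction",
    )
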
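"""Shared statistical core: rank-sum comparisons between pair classes."""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = ["wilcoxon_rank_sum"]

Alternative = Literal["two_sided", "greater", "less"]


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: Alternative = "two_sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Small tie-free samples are tested by exact permutation enumeration;
    otherwise the tie-corrected normal approximation is used.  Returns
    ``(statistic, p_value)``; the statistic is the Mann-Whitney U of
    ``group_a``.  ``alternative="greater"`` tests whether values in
    ``group_a`` tend to be larger than in ``group_b``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.mannwhitneyu(
        a, b, alternative=alternative.replace("two_sided", "two-sided"), method="auto"
    )
    return float(res.statistic), float(res.pvalue)
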
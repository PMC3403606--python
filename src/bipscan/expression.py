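"""Expression processing: probeset collapse, coexpression, and tissue
specificity.

Expression matrices are pandas DataFrames with gene (or probeset) rows
and sample/cell-type columns of non-negative values, e.g. an
RMA-normalised microarray compendium.  A gene measured by several
probesets takes the arithmetic mean of their rows.  Replicate arrays of
the same cell type may be averaged before computing statistics.

Tissue specificity is the tau index

    tau = sum_i (1 - E_i / E_max) / (n - 1),     0 <= tau <= 1,

which is 0 for a perfectly uniform (housekeeping-like) profile and 1 for
single-tissue expression.  Coexpression of a gene pair is the Pearson
correlation of the two expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .stats import Alternative, wilcoxon_rank_sum

__all__ = [
    "TauResult",
    "collapse_probesets",
    "collapse_replicates",
    "tau_specificity",
    "tau_table",
    "pair_coexpression",
    "compare_pair_classes",
]


@dataclass(frozen=True)
class TauResult:
    gene: str
    tau: float | None
    n: int
    e_max: float


def collapse_probesets(
    matrix: pd.DataFrame, probeset_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Gene-level matrix: columnwise arithmetic mean over a gene's probesets.

    Probesets absent from the map are dropped; a mapped probeset missing
    from the matrix raises.  Genes whose probesets are all absent are
    excluded (none can remain mapped-but-missing by construction).
    """
    missing = [p for p in probeset_to_gene if p not in matrix.index]
    if missing:
        raise KeyError(f"probesets in map but not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    mapped = matrix.loc[list(probeset_to_gene)]
    genes = pd.Series({p: probeset_to_gene[p] for p in mapped.index}, name="gene")
    out = mapped.groupby(genes).mean()
    out.index.name = "gene"
    return out


def collapse_replicates(
    matrix: pd.DataFrame, sample_to_celltype: Mapping[str, str]
) -> pd.DataFrame:
    """Average replicate arrays of the same cell type (columnwise groups)."""
    groups = pd.Series({c: sample_to_celltype.get(c, c) for c in matrix.columns})
    return matrix.T.groupby(groups).mean().T


def tau_specificity(profile: Sequence[float], gene: str = "") -> TauResult:
    """Tissue-specificity index tau for one expression profile.

    Undefined (tau=None) for an all-zero profile (E_max = 0).
    """
    e = np.asarray(profile, dtype=float)
    n = e.size
    if n < 2:
        raise ValueError("tau requires at least 2 samples")
    if np.any(e < 0):
        raise ValueError("expression values must be non-negative")
    e_max = float(e.max())
    if e_max == 0.0:
        return TauResult(gene=gene, tau=None, n=n, e_max=0.0)
    tau = float(np.sum(1.0 - e / e_max) / (n - 1))
    return TauResult(gene=gene, tau=tau, n=n, e_max=e_max)


def tau_table(matrix: pd.DataFrame) -> pd.Series:
    """tau per gene row; all-zero genes come out as NaN."""
    vals = matrix.to_numpy(dtype=float)
    e_max = vals.max(axis=1)
    n = vals.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.sum(1.0 - vals / e_max[:, None], axis=1) / (n - 1)
    tau[e_max == 0] = np.nan
    return pd.Series(tau, index=matrix.index, name="tau")


def pair_coexpression(
    matrix: pd.DataFrame,
    pairs_by_class: Mapping[str, Iterable[tuple[str, str]]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pearson r per gene pair, tagged with its class.

    ``pairs_by_class`` maps a class label (BIP, rH2H, H2T, random, ...)
    to (gene_a, gene_b) id pairs.  Pairs with a gene missing from the
    matrix or with a constant profile are skipped; the per-class skip
    counts are returned alongside the table.
    """
    vals = matrix.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(matrix.index)}
    constant = np.ptp(vals, axis=1) == 0
    rows = []
    skipped: dict[str, int] = {}
    for clazz, pairs in pairs_by_class.items():
        skipped[clazz] = 0
        for a, b in pairs:
            ia, ib = index.get(a), index.get(b)
            if ia is None or ib is None or constant[ia] or constant[ib]:
                skipped[clazz] += 1
                continue
            r = float(sstats.pearsonr(vals[ia], vals[ib]).statistic)
            rows.append((a, b, clazz, r))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pair_class", "r"])
    return table, skipped


def compare_pair_classes(
    table: pd.DataFrame,
    class_a: str,
    class_b: str,
    alternative: Alternative = "greater",
) -> tuple[float, float]:
    """Rank-sum comparison of coexpression between two pair classes.

    The directional default (``greater``) asks whether ``class_a`` pairs
    are more strongly coexpressed than ``class_b`` pairs.
    """
    a = table.loc[table["pair_class"] == class_a, "r"]
    b = table.loc[table["pair_class"] == class_b, "r"]
    return wilcoxon_rank_sum(a, b, alternative=alternative)
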
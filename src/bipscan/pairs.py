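"""Adjacent gene-pair enumeration, orientation classes, and bip calling.

Adjacent gene pairs fall into three orientation categories:

* ``H2H`` (head-to-head, divergent): opposite strands, the lower-TSS gene
  on '-' and the higher-TSS gene on '+', so transcription points away
  from the shared intergenic region.
* ``T2T`` (tail-to-tail, convergent): the reverse opposite-strand
  arrangement.
* ``H2T`` (head-to-tail): both genes on the same strand.

Bidirectional gene pairs (bip) are H2H pairs whose TSS distance is
strictly below a threshold, 1000 bp by default.  H2H pairs at or above
the threshold are "remote head-to-head" (rH2H) pairs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .genome import Gene, GenomeAnnotation, TssMode, sort_by_tss, tss

__all__ = [
    "AdjacentPair",
    "PairClassSet",
    "enumerate_adjacent_pairs",
    "identify_bip",
    "bip_percentage",
    "sample_random_pairs",
    "write_pair_table",
]

Category = Literal["H2H", "H2T", "T2T"]
H2HMode = Literal["divergent_only", "all_opposite"]


@dataclass(frozen=True, slots=True)
class AdjacentPair:
    """Two neighbouring genes; ``gene_a`` has the lower (or tied) TSS."""

    gene_a: Gene
    gene_b: Gene
    category: Category
    tss_distance: int

    @property
    def chromosome(self) -> str:
        return self.gene_a.chromosome

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a.id, self.gene_b.id))


def _classify(lower: Gene, upper: Gene) -> Category:
    if lower.strand == upper.strand:
        return "H2T"
    return "H2H" if lower.strand == "-" else "T2T"


def enumerate_adjacent_pairs(
    sorted_genes: dict[str, list[Gene]], tss_mode: TssMode = "five_prime"
) -> list[AdjacentPair]:
    """All (k-1) neighbouring pairs per chromosome with k genes.

    ``sorted_genes`` is the output of :func:`bipscan.genome.sort_by_tss`;
    each consecutive pair in TSS order yields one :class:`AdjacentPair`.
    Overlapping genes are kept; the distance is always |TSS_a - TSS_b|.
    """
    pairs = []
    for genes in sorted_genes.values():
        for a, b in zip(genes, genes[1:]):
            pairs.append(
                AdjacentPair(
                    gene_a=a,
                    gene_b=b,
                    category=_classify(a, b),
                    tss_distance=abs(tss(a, tss_mode) - tss(b, tss_mode)),
                )
            )
    return pairs


@dataclass
class PairClassSet:
    """The four gene-pair classes compared throughout the analysis."""

    bip: list[AdjacentPair] = field(default_factory=list)
    rh2h: list[AdjacentPair] = field(default_factory=list)
    h2t: list[AdjacentPair] = field(default_factory=list)
    t2t: list[AdjacentPair] = field(default_factory=list)
    random_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_bidirectional_promoters(self) -> int:
        return len(self.bip)

    @property
    def bidirectional_genes(self) -> set[str]:
        return {gid for p in self.bip for gid in (p.gene_a.id, p.gene_b.id)}

    @property
    def n_bidirectional_genes(self) -> int:
        return len(self.bidirectional_genes)

    def genes_in_multiple_bip_pairs(self) -> set[str]:
        """Genes shared between two bip pairs (why gene count < 2x promoters)."""
        seen: set[str] = set()
        multi: set[str] = set()
        for p in self.bip:
            for gid in (p.gene_a.id, p.gene_b.id):
                (multi if gid in seen else seen).add(gid)
        return multi

    def classes(self) -> dict[str, list[AdjacentPair]]:
        return {"BIP": self.bip, "rH2H": self.rh2h, "H2T": self.h2t, "T2T": self.t2t}


def identify_bip(
    pairs: Iterable[AdjacentPair],
    threshold: int = 1000,
    h2h_mode: H2HMode = "divergent_only",
) -> PairClassSet:
    """Partition adjacent pairs into bip / rH2H / H2T / T2T classes.

    A head-to-head pair is bidirectional when its TSS distance is
    strictly less than ``threshold`` (default 1 kb).  Under
    ``h2h_mode="all_opposite"`` convergent (T2T) pairs are treated as
    head-to-head too, reproducing analyses that lump all opposite-strand
    neighbours together.
    """
    if threshold <= 0:
        raise ValueError("threshold must be a positive number of base pairs")
    out = PairClassSet()
    h2h_cats = {"H2H"} if h2h_mode == "divergent_only" else {"H2H", "T2T"}
    for p in pairs:
        if p.category in h2h_cats:
            (out.bip if p.tss_distance < threshold else out.rh2h).append(p)
        elif p.category == "H2T":
            out.h2t.append(p)
        else:
            out.t2t.append(p)
    return out


def bip_percentage(n_bidirectional_genes: int, n_total_genes: int) -> float:
    """Percentage of genes under bidirectional control, to 2 decimals."""
    if n_total_genes <= 0:
        raise ValueError("n_total_genes must be positive")
    if not 0 <= n_bidirectional_genes <= n_total_genes:
        raise ValueError("need 0 <= n_bidirectional_genes <= n_total_genes")
    return round(100.0 * n_bidirectional_genes / n_total_genes, 2)


def sample_random_pairs(
    annotation: GenomeAnnotation, n: int = 20000, seed: int | None = None
) -> list[tuple[str, str]]:
    """Uniform random pairs of distinct genes, the coexpression control set.

    Pairs are drawn genome-wide with replacement across pairs but without
    repetition within a pair; reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = [g.id for g in annotation.genes]
    if len(ids) < 2:
        raise ValueError("need at least 2 genes to sample pairs")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        i, j = rng.choice(len(ids), size=2, replace=False)
        out.append((ids[i], ids[j]))
    return out


def write_pair_table(pairs: Iterable[AdjacentPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "chromosome", "category", "tss_distance"])
        for p in pairs:
            writer.writerow([p.gene_a.id, p.gene_b.id, p.chromosome, p.category, p.tss_distance])
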
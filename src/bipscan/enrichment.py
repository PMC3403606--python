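"""Hypergeometric enrichment of bidirectional genes in pathway gene sets.

For one pathway: the universe holds N protein-coding genes, N1 of them
in the pathway, N2 of them bidirectional, and N0 bidirectional genes are
observed inside the pathway.  Under the null that bidirectional genes
land in the pathway at random, the in-pathway count is hypergeometric,
and the enrichment p-value is the upper tail

    P = 1 - sum_{i=0}^{N0-1} C(N1, i) C(N-N1, N2-i) / C(N, N2),

the probability of observing at least N0.  A pathway is called enriched
at p < alpha (default 0.05, uncorrected); an optional Benjamini-Hochberg
correction is available but off by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment_p",
    "enrich_all",
    "cross_species_pathway_counts",
    "read_pathway_table",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    N: int
    N1: int
    N2: int
    N0: int
    p_value: float
    enriched: bool


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_enrichment_p(N: int, N1: int, N2: int, N0: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= N0), in log space.

    Validates the count constraints (N0 <= min(N1, N2); N1, N2 <= N).
    N0 = 0 gives exactly 1.
    """
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise ValueError("need 0 <= N1 <= N and 0 <= N2 <= N")
    if not (0 <= N0 <= min(N1, N2)):
        raise ValueError("need 0 <= N0 <= min(N1, N2)")
    lo = max(0, N1 + N2 - N)  # smallest feasible overlap
    if N0 <= lo:
        return 1.0
    # tail sum i = N0 .. min(N1, N2) of the hypergeometric pmf
    i = np.arange(N0, min(N1, N2) + 1)
    log_pmf = _log_comb(N1, i) + _log_comb(N - N1, N2 - i) - _log_comb(N, N2)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrich_all(
    pathways: Mapping[str, tuple[str, set[str]]],
    bidirectional_genes: set[str],
    universe: set[str],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """One enrichment test per pathway, sorted by ascending p-value.

    ``pathways`` maps pathway id -> (name, gene set); pathway genes must
    be contained in the universe (all protein-coding genes of the
    species).  ``enriched`` is p < alpha on the raw p-value, or on the
    BH-adjusted p-value when ``bh_correct`` is set.
    """
    if not universe:
        raise ValueError("empty gene universe")
    stray = {g for _, (_, genes) in pathways.items() for g in genes} - universe
    if stray:
        raise ValueError(f"pathway genes outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    bip = bidirectional_genes & universe
    N2 = len(bip)
    raw = []
    for pid, (name, genes) in pathways.items():
        N1 = len(genes)
        N0 = len(genes & bip)
        raw.append((pid, name, N1, N0, hypergeom_enrichment_p(N, N1, N2, N0)))
    pvals = np.array([r[4] for r in raw])
    effective = _bh_adjust(pvals) if bh_correct else pvals
    results = [
        EnrichmentResult(
            pathway_id=pid,
            pathway_name=name,
            N=N,
            N1=N1,
            N2=N2,
            N0=N0,
            p_value=p,
            enriched=bool(eff < alpha),
        )
        for (pid, name, N1, N0, p), eff in zip(raw, effective)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def cross_species_pathway_counts(
    per_species: Mapping[str, Iterable[EnrichmentResult]],
) -> dict[str, int]:
    """Per pathway name, the number of species where it is enriched.

    Pathways enriched in no species are absent from the output.
    """
    counts: dict[str, int] = {}
    for results in per_species.values():
        for r in results:
            if r.enriched:
                counts[r.pathway_name] = counts.get(r.pathway_name, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def read_pathway_table(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """TSV ``pathway_id pathway_name gene_id`` -> pathway db."""
    out: dict[str, tuple[str, set[str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            name, genes = out.setdefault(row["pathway_id"], (row["pathway_name"], set()))
            genes.add(row["gene_id"])
    return out


def write_enrichment_table(
    results: Iterable[EnrichmentResult], path: str | Path, gene_class: str = "BIP"
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["pathway_id", "pathway_name", "N", "N1", "N2", "N0", "p_value", "enriched", "gene_class"]
        )
        for r in results:
            writer.writerow(
                [r.pathway_id, r.pathway_name, r.N, r.N1, r.N2, r.N0, f"{r.p_value:.6g}", int(r.enriched), gene_class]
            )
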
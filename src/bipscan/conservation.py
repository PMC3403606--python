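"""Conservation of bidirectional pairs through one-to-one orthologs.

A bidirectional pair in species A is *conserved* (cBIP) when both genes
have one-to-one orthologs in species B and those two orthologs are
themselves partners of a single bidirectional pair in B.  Pairs where
either gene lacks an ortholog are excluded from the discussed universe
(reason ``ortholog_missing``); the remaining non-conserved pairs are
species-specific (sBIP, reason ``ortholog_not_bip``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .pairs import AdjacentPair

__all__ = [
    "OrthologMap",
    "ConservationCall",
    "classify_conservation",
    "split_gene_sets",
    "read_ortholog_table",
    "write_conservation_report",
]

Call = Literal["cBIP", "sBIP", "excluded"]
Reason = Literal["partner_pair_bip", "ortholog_missing", "ortholog_not_bip"]


class OrthologMap:
    """Strictly one-to-one gene correspondences between two species."""

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        self.a_to_b: dict[str, str] = {}
        self.b_to_a: dict[str, str] = {}
        for a, b in pairs:
            if a in self.a_to_b or b in self.b_to_a:
                raise ValueError(f"ortholog map is not one-to-one at ({a}, {b})")
            self.a_to_b[a] = b
            self.b_to_a[b] = a

    def __len__(self) -> int:
        return len(self.a_to_b)


@dataclass(frozen=True)
class ConservationCall:
    pair_id: str
    gene_a: str
    gene_b: str
    call: Call
    reason: Reason


def _pair_id(p: AdjacentPair) -> str:
    return f"{p.gene_a.id}|{p.gene_b.id}"


def classify_conservation(
    bip_a: Iterable[AdjacentPair],
    bip_b: Iterable[AdjacentPair],
    orthologs: OrthologMap,
    direction: Literal["a_to_b", "b_to_a"] = "a_to_b",
) -> list[ConservationCall]:
    """Call each species-A bip pair cBIP / sBIP / excluded.

    ``direction="b_to_a"`` runs the symmetric classification of species-B
    pairs through the inverse map.  A cBIP call requires the two
    orthologs to be partners of the *same* pair in the other species,
    not merely each bidirectional somewhere.
    """
    fwd = orthologs.a_to_b if direction == "a_to_b" else orthologs.b_to_a
    query, target = (bip_a, bip_b) if direction == "a_to_b" else (bip_b, bip_a)
    target_keys = {p.key for p in target}
    calls = []
    for p in query:
        oa, ob = fwd.get(p.gene_a.id), fwd.get(p.gene_b.id)
        if oa is None or ob is None:
            calls.append(ConservationCall(_pair_id(p), p.gene_a.id, p.gene_b.id, "excluded", "ortholog_missing"))
        elif frozenset((oa, ob)) in target_keys:
            calls.append(ConservationCall(_pair_id(p), p.gene_a.id, p.gene_b.id, "cBIP", "partner_pair_bip"))
        else:
            calls.append(ConservationCall(_pair_id(p), p.gene_a.id, p.gene_b.id, "sBIP", "ortholog_not_bip"))
    return calls


def split_gene_sets(calls: Iterable[ConservationCall]) -> tuple[set[str], set[str]]:
    """Genes of conserved pairs and of species-specific (discussed) pairs.

    A gene sitting in two pairs may appear in both sets; disjointness is
    reported by the caller, not enforced here.
    """
    cbip: set[str] = set()
    sbip: set[str] = set()
    for c in calls:
        if c.call == "cBIP":
            cbip.update((c.gene_a, c.gene_b))
        elif c.call == "sBIP":
            sbip.update((c.gene_a, c.gene_b))
    return cbip, sbip


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """TSV ``gene_a gene_b`` -> one-to-one ortholog map."""
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pairs.append((row["gene_a"], row["gene_b"]))
    return OrthologMap(pairs)


def write_conservation_report(calls: Iterable[ConservationCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pair_id", "call", "reason"])
        for c in calls:
            writer.writerow([c.pair_id, c.call, c.reason])
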
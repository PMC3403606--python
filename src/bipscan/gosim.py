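"""Resnik semantic similarity over a Gene Ontology-style DAG.

Terms live in one of three namespaces (BP, MF, CC), each rooted, with
directed acyclic is_a edges child -> parent.  Direct gene annotations
are extended to the ancestor closure; the information content of a term
is ic(t) = -ln p(t), where p(t) is the fraction of namespace-annotated
genes whose closure contains t (so ic(root) = 0).  The similarity of two
genes is aggregated over the information content of most informative
common ancestors (MICA) of their annotated term pairs — by default the
maximum over all cross pairs, which for closed annotation sets equals
the maximum ic over the intersection of the two closures.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

from .stats import Alternative, wilcoxon_rank_sum

__all__ = [
    "OntologyDAG",
    "load_ontology_edges",
    "load_obo",
    "read_annotation_pairs",
    "extend_annotations",
    "term_ic",
    "gene_pair_resnik",
    "compare_similarity_classes",
]

NAMESPACES = ("BP", "MF", "CC")
_OBO_NAMESPACE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

Aggregation = Literal["max", "best_match_average"]


@dataclass
class OntologyDAG:
    """is_a DAG with one root per namespace.

    ``graph`` holds child -> parent edges; nodes carry a ``namespace``
    attribute in {BP, MF, CC}.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology edges contain a cycle")
        self._roots: dict[str, str] = {}
        for ns in self.namespaces():
            roots = [
                n
                for n, d in self.graph.nodes(data=True)
                if d.get("namespace") == ns and self.graph.out_degree(n) == 0
            ]
            if len(roots) != 1:
                raise ValueError(f"namespace {ns} must have exactly one root, found {roots}")
            self._roots[ns] = roots[0]

    def namespaces(self) -> list[str]:
        return sorted({d.get("namespace") for _, d in self.graph.nodes(data=True)})

    def root(self, namespace: str) -> str:
        return self._roots[namespace]

    def namespace_of(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]

    def ancestors(self, term: str) -> set[str]:
        """The term plus all is_a ancestors up to the namespace root."""
        return {term} | nx.descendants(self.graph, term)


def load_ontology_edges(path: str | Path) -> OntologyDAG:
    """Edge-list TSV ``child parent namespace`` -> ontology DAG.

    Roots are listed with an empty parent field (or parent == child is
    tolerated and ignored).
    """
    g = nx.DiGraph()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            child, parent, ns = row["child"], row["parent"], row["namespace"]
            g.add_node(child, namespace=ns)
            if parent and parent != child:
                g.add_node(parent, namespace=ns)
                g.add_edge(child, parent)
    return OntologyDAG(g)


def load_obo(path: str | Path) -> OntologyDAG:
    """Minimal OBO reader (is_a edges only), via obonet."""
    import obonet

    raw = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for node, data in raw.nodes(data=True):
        ns = _OBO_NAMESPACE.get(data.get("namespace", ""), data.get("namespace", ""))
        g.add_node(node, namespace=ns)
    for child, parent, key in raw.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return OntologyDAG(g)


def read_annotation_pairs(path: str | Path) -> dict[str, set[str]]:
    """Gene->terms from a TSV with ``gene_id`` and ``term_id`` columns.

    GAF-like files work too: any extra columns are ignored.
    """
    out: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.setdefault(row["gene_id"], set()).add(row["term_id"])
    return out


def extend_annotations(
    direct: Mapping[str, Iterable[str]], dag: OntologyDAG
) -> dict[str, dict[str, set[str]]]:
    """Close each gene's direct annotations under is_a ancestry.

    Returns ``{namespace: {gene: closed term set}}``.  Unknown term ids
    raise with the full offender list.
    """
    unknown = sorted(
        {t for terms in direct.values() for t in terms if t not in dag.graph}
    )
    if unknown:
        raise KeyError(f"terms not in ontology: {unknown}")
    closure_cache: dict[str, set[str]] = {}
    closed: dict[str, dict[str, set[str]]] = {}
    for gene, terms in direct.items():
        for t in terms:
            if t not in closure_cache:
                closure_cache[t] = dag.ancestors(t)
            ns = dag.namespace_of(t)
            closed.setdefault(ns, {}).setdefault(gene, set()).update(closure_cache[t])
    return closed


def term_ic(
    closed_ns: Mapping[str, set[str]], dag: OntologyDAG, namespace: str
) -> dict[str, float]:
    """Information content per term: ic = -ln(annotated fraction).

    ``closed_ns`` is one namespace's gene -> closed-term-set map; p(t) is
    normalised by the number of genes annotated in that namespace, so the
    root always has p=1, ic=0.  Terms with no annotated gene are absent.
    """
    n_genes = len(closed_ns)
    if n_genes == 0:
        raise ValueError(f"no annotated genes in namespace {namespace}")
    counts: dict[str, int] = {}
    for terms in closed_ns.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n_genes) for t, c in counts.items()}


def gene_pair_resnik(
    gene_a: str,
    gene_b: str,
    closed_ns: Mapping[str, set[str]],
    ic: Mapping[str, float],
    dag: OntologyDAG | None = None,
    aggregation: Aggregation = "max",
    direct_ns: Mapping[str, set[str]] | None = None,
) -> float | None:
    """Resnik similarity of two genes within one namespace.

    Returns None (pair skipped) if either gene is unannotated in the
    namespace.  ``max`` aggregation: the ic of the most informative
    common ancestor over all cross term pairs, which for closed
    annotation sets is simply the highest-ic term shared by the two
    closures.  ``best_match_average``: for each *directly* annotated
    term of one gene take the best MICA ic against the other gene's
    direct terms, then average over both directions (requires ``dag``
    and ``direct_ns``, the pre-closure annotations).
    """
    terms_a = closed_ns.get(gene_a)
    terms_b = closed_ns.get(gene_b)
    if not terms_a or not terms_b:
        return None
    if aggregation == "max":
        common = terms_a & terms_b
        return max((ic.get(t, 0.0) for t in common), default=0.0)
    if aggregation == "best_match_average":
        if dag is None or direct_ns is None:
            raise ValueError("best_match_average needs the ontology DAG and direct annotations")
        direct_a = direct_ns[gene_a]
        direct_b = direct_ns[gene_b]

        def mica_ic(t1: str, t2: str) -> float:
            anc = dag.ancestors(t1) & dag.ancestors(t2)
            return max((ic.get(t, 0.0) for t in anc), default=0.0)

        def best_row(src: set[str], dst: set[str]) -> float:
            return sum(max(mica_ic(s, d) for d in dst) for s in src) / len(src)

        return 0.5 * (best_row(direct_a, direct_b) + best_row(direct_b, direct_a))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def compare_similarity_classes(
    sims_by_class: Mapping[str, Iterable[float]],
    class_a: str,
    class_b: str,
    alternative: Alternative = "greater",
) -> tuple[float, float]:
    """Rank-sum comparison of pair-similarity distributions between classes."""
    return wilcoxon_rank_sum(
        list(sims_by_class[class_a]), list(sims_by_class[class_b]), alternative=alternative
    )
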
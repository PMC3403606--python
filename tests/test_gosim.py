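import itertools
import math

import networkx as nx
import numpy as np
import pytest

from bipscan.gosim import (
    OntologyDAG,
    compare_similarity_classes,
    extend_annotations,
    gene_pair_resnik,
    load_ontology_edges,
    term_ic,
)


def toy_dag():
    """12-term BP DAG: root, 3 mid terms, 8 leaves, one multi-parent leaf."""
    g = nx.DiGraph()
    edges = [
        ("m1", "root"), ("m2", "root"), ("m3", "root"),
        ("l1", "m1"), ("l2", "m1"), ("l3", "m2"), ("l4", "m2"),
        ("l5", "m3"), ("l6", "m3"), ("l7", "m3"),
        ("l8", "m1"), ("l8", "m2"),  # diamond
    ]
    for c, p in edges:
        g.add_node(c, namespace="BP")
        g.add_node(p, namespace="BP")
        g.add_edge(c, p)
    return OntologyDAG(g)


TOY_GENES = {
    "gA": {"l1", "l3"},
    "gB": {"l2"},
    "gC": {"l8"},
    "gD": {"l5", "l7"},
    "gE": {"l4"},
}


def brute_force_resnik(dag, ic, terms_a, terms_b, aggregation="max"):
    """Exhaustive MICA search over every cross term pair."""

    def mica(t1, t2):
        common = dag.ancestors(t1) & dag.ancestors(t2)
        return max((ic.get(t, 0.0) for t in common), default=0.0)

    cross = [mica(a, b) for a, b in itertools.product(terms_a, terms_b)]
    if aggregation == "max":
        return max(cross)
    rows = [max(mica(a, b) for b in terms_b) for a in terms_a]
    cols = [max(mica(a, b) for a in terms_a) for b in terms_b]
    return 0.5 * (sum(rows) / len(rows) + sum(cols) / len(cols))


class TestDagAndClosure:
    def test_cycle_rejected(self):
        g = nx.DiGraph()
        g.add_node("a", namespace="BP")
        g.add_node("b", namespace="BP")
        g.add_edge("a", "b")
        g.add_edge("b", "a")
        with pytest.raises(ValueError, match="cycle"):
            OntologyDAG(g)

    def test_root_only_annotation(self):
        dag = toy_dag()
        closed = extend_annotations({"g": {"root"}}, dag)
        assert closed["BP"]["g"] == {"root"}

    def test_chain_closure(self):
        dag = toy_dag()
        closed = extend_annotations({"g": {"l1"}}, dag)
        assert closed["BP"]["g"] == {"l1", "m1", "root"}

    def test_multi_parent_closure(self):
        dag = toy_dag()
        closed = extend_annotations({"g": {"l8"}}, dag)
        assert closed["BP"]["g"] == {"l8", "m1", "m2", "root"}

    def test_unknown_term_listed(self):
        with pytest.raises(KeyError, match="nope"):
            extend_annotations({"g": {"nope"}}, toy_dag())

    def test_random_dag_closure_matches_warshall(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            # random 30-term DAG over a topological order
            n = 30
            g = nx.DiGraph()
            for i in range(n):
                g.add_node(f"t{i}", namespace="BP")
            for i in range(n - 1):
                # every non-root gets >= 1 parent later in the order
                parents = rng.choice(np.arange(i + 1, n), size=min(int(rng.integers(1, 3)), n - 1 - i), replace=False)
                for p in parents:
                    g.add_edge(f"t{i}", f"t{p}")
            dag = OntologyDAG(g)
            # boolean transitive closure by repeated squaring (Warshall-style)
            adj = np.eye(n, dtype=bool)
            for c, p in g.edges():
                adj[int(c[1:]), int(p[1:])] = True
            closure = adj.copy()
            for _ in range(n):
                new = closure | (closure @ closure)
                if (new == closure).all():
                    break
                closure = new
            genes = {f"g{i}": {f"t{int(rng.integers(n))}"} for i in range(10)}
            closed = extend_annotations(genes, dag)["BP"]
            for gene, terms in genes.items():
                t = int(next(iter(terms))[1:])
                expected = {f"t{j}" for j in range(n) if closure[t, j]}
                assert closed[gene] == expected


class TestTermIC:
    def test_root_ic_zero_and_monotone(self):
        dag = toy_dag()
        closed = extend_annotations(TOY_GENES, dag)["BP"]
        ic = term_ic(closed, dag, "BP")
        assert ic["root"] == 0.0
        for child, parent in dag.graph.edges():
            if child in ic and parent in ic:
                assert ic[child] >= ic[parent]

    def test_one_in_ten_annotation(self):
        dag = toy_dag()
        genes = {f"g{i}": {"l1" if i == 0 else "l5"} for i in range(10)}
        closed = extend_annotations(genes, dag)["BP"]
        ic = term_ic(closed, dag, "BP")
        assert ic["l1"] == pytest.approx(-math.log(0.1))


class TestGenePairResnik:
    def test_self_similarity_is_leaf_ic(self):
        dag = toy_dag()
        closed = extend_annotations({"g": {"l1"}, "h": {"l1"}}, dag)["BP"]
        ic = term_ic(closed, dag, "BP")
        assert gene_pair_resnik("g", "h", closed, ic) == pytest.approx(ic["l1"])

    def test_root_only_overlap_is_zero(self):
        dag = toy_dag()
        closed = extend_annotations({"g": {"l1"}, "h": {"l5"}}, dag)["BP"]
        ic = term_ic(closed, dag, "BP")
        assert gene_pair_resnik("g", "h", closed, ic) == 0.0

    def test_unannotated_gene_skipped(self):
        dag = toy_dag()
        closed = extend_annotations({"g": {"l1"}}, dag)["BP"]
        ic = term_ic(closed, dag, "BP")
        assert gene_pair_resnik("g", "missing", closed, ic) is None

    @pytest.mark.parametrize("aggregation", ["max", "best_match_average"])
    def test_matches_brute_force_mica(self, aggregation):
        dag = toy_dag()
        closed = extend_annotations(TOY_GENES, dag)["BP"]
        ic = term_ic(closed, dag, "BP")
        for ga, gb in itertools.combinations(TOY_GENES, 2):
            got = gene_pair_resnik(
                ga, gb, closed, ic, dag=dag, aggregation=aggregation, direct_ns=TOY_GENES
            )
            expected = brute_force_resnik(dag, ic, TOY_GENES[ga], TOY_GENES[gb], aggregation)
            assert got == pytest.approx(expected), (ga, gb)

    def test_symmetry(self):
        dag = toy_dag()
        closed = extend_annotations(TOY_GENES, dag)["BP"]
        ic = term_ic(closed, dag, "BP")
        for ga, gb in itertools.combinations(TOY_GENES, 2):
            assert gene_pair_resnik(ga, gb, closed, ic) == gene_pair_resnik(gb, ga, closed, ic)

    def test_adding_annotation_never_decreases_max_similarity(self):
        dag = toy_dag()
        base = {"g": {"l1"}, "h": {"l3"}}
        closed = extend_annotations(base, dag)["BP"]
        ic = term_ic(extend_annotations(TOY_GENES | base, dag)["BP"], dag, "BP")
        before = gene_pair_resnik("g", "h", closed, ic)
        grown = extend_annotations({"g": {"l1", "l4"}, "h": {"l3"}}, dag)["BP"]
        after = gene_pair_resnik("g", "h", grown, ic)
        assert after >= before

    def test_similarity_bounded_by_own_max_ic(self):
        dag = toy_dag()
        closed = extend_annotations(TOY_GENES, dag)["BP"]
        ic = term_ic(closed, dag, "BP")
        for ga, gb in itertools.combinations(TOY_GENES, 2):
            sim = gene_pair_resnik(ga, gb, closed, ic)
            cap = min(
                max(ic.get(t, 0.0) for t in closed[ga]),
                max(ic.get(t, 0.0) for t in closed[gb]),
            )
            assert sim <= cap + 1e-12


class TestEdgeListIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "ont.tsv"
        path.write_text(
            "child\tparent\tnamespace\n"
            "root\t\tBP\n"
            "m1\troot\tBP\n"
            "l1\tm1\tBP\n"
        )
        dag = load_ontology_edges(path)
        assert dag.root("BP") == "root"
        assert dag.ancestors("l1") == {"l1", "m1", "root"}


class TestOboReader:
    OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: child process
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: leaf process
namespace: biological_process
is_a: GO:0000002 ! child process
"""

    def test_minimal_obo_round_trip(self, tmp_path):
        from bipscan.gosim import load_obo

        path = tmp_path / "mini.obo"
        path.write_text(self.OBO)
        dag = load_obo(path)
        assert dag.root("BP") == "GO:0000001"
        assert dag.ancestors("GO:0000003") == {"GO:0000003", "GO:0000002", "GO:0000001"}


class TestCompareSimilarityClasses:
    def test_identical_groups(self):
        sims = {"a": [0.1, 0.5, 0.9, 1.2], "b": [0.1, 0.5, 0.9, 1.2]}
        _, p = compare_similarity_classes(sims, "a", "b", alternative="two_sided")
        assert p >= 0.99

    def test_planted_cc_elevation_detected_cc_only(self):
        """Shared CC leaf annotations for planted pairs: the CC comparison is
        significant, BP (independent annotations) is not."""
        from bipscan.simulate import (
            SynthesisConfig,
            generate_annotation,
            generate_go_annotations,
            generate_ontology,
        )
        from bipscan.genome import sort_by_tss
        from bipscan.pairs import enumerate_adjacent_pairs, identify_bip, sample_random_pairs

        cc_hits = 0
        bp_hits = 0
        n_rerun = 10
        for seed in range(n_rerun):
            cfg = SynthesisConfig(seed=2000 + seed, genes_per_chromosome=150, n_chromosomes=2, bip_fraction=0.2)
            ann, truth = generate_annotation(cfg)
            dag = generate_ontology(cfg)
            direct = generate_go_annotations(ann, truth, dag, cfg)
            closed = extend_annotations(direct, dag)
            pcs = identify_bip(enumerate_adjacent_pairs(sort_by_tss(ann)))
            rnd = sample_random_pairs(ann, n=500, seed=seed)
            for ns, counter in (("CC", "cc"), ("BP", "bp")):
                ic = term_ic(closed[ns], dag, ns)
                sims = {"BIP": [], "random": []}
                for tag, plist in (("BIP", [(p.gene_a.id, p.gene_b.id) for p in pcs.bip]), ("random", rnd)):
                    for a, b in plist:
                        s = gene_pair_resnik(a, b, closed[ns], ic)
                        if s is not None:
                            sims[tag].append(s)
                _, p = compare_similarity_classes(sims, "BIP", "random", alternative="greater")
                if ns == "CC":
                    cc_hits += p < 0.01
                else:
                    bp_hits += p < 0.01
        assert cc_hits >= 9
        assert bp_hits <= 1
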
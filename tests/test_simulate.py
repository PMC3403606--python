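import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bipscan.expression import tau_table
from bipscan.genome import sort_by_tss, write_annotation_tsv
from bipscan.pairs import enumerate_adjacent_pairs, identify_bip
from bipscan.simulate import (
    SynthesisConfig,
    generate_annotation,
    generate_dataset,
    generate_expression,
    generate_ontology,
    generate_pathways,
    octet_configs,
    write_dataset,
)


def found_bip_keys(annotation):
    pcs = identify_bip(enumerate_adjacent_pairs(sort_by_tss(annotation)))
    return {p.key for p in pcs.bip}


class TestGenerateAnnotation:
    def test_no_planted_pairs_means_no_bip_calls(self):
        cfg = SynthesisConfig(seed=1, bip_fraction=0.0, genes_per_chromosome=300)
        ann, truth = generate_annotation(cfg)
        assert truth.planted_bip == []
        # false positives from the major component are possible but rare
        assert len(found_bip_keys(ann)) <= 2

    def test_planted_count_recovered_within_binomial_ci(self):
        cfg = SynthesisConfig(seed=7, bip_fraction=0.3, genes_per_chromosome=400)
        ann, truth = generate_annotation(cfg)
        found = found_bip_keys(ann)
        planted = {frozenset(p) for p in truth.planted_bip}
        lo, hi = stats.binom.interval(0.99, len(planted), 1.0)
        assert lo <= len(found & planted) <= hi
        assert len(planted) == 300  # 0.3 * 2000 genes / 2

    def test_same_seed_byte_identical_tsv(self, tmp_path):
        cfg = SynthesisConfig(seed=5, genes_per_chromosome=100, n_chromosomes=2)
        for name in ("a", "b"):
            ann, _ = generate_annotation(cfg)
            write_annotation_tsv(ann, tmp_path / f"{name}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_minor_gap_marginal_distribution(self):
        """Planted TSS gaps follow the truncated log-normal minor component."""
        cfg = SynthesisConfig(seed=9, bip_fraction=0.5, genes_per_chromosome=1000, n_chromosomes=2)
        ann, truth = generate_annotation(cfg)
        pcs = identify_bip(enumerate_adjacent_pairs(sort_by_tss(ann)))
        planted = {frozenset(p) for p in truth.planted_bip}
        d = np.log10([p.tss_distance for p in pcs.bip if p.key in planted])
        assert d.size >= 450

        def trunc_cdf(x):
            a = stats.norm.cdf(0, cfg.minor_log10_mean, cfg.minor_log10_sd)
            b = stats.norm.cdf(3, cfg.minor_log10_mean, cfg.minor_log10_sd)
            return (stats.norm.cdf(x, cfg.minor_log10_mean, cfg.minor_log10_sd) - a) / (b - a)

        # rounding to integer bp perturbs the sample slightly; KS at alpha 1e-4
        assert stats.kstest(d, trunc_cdf).pvalue > 1e-4


class TestGenerateExpression:
    def test_perfect_rho_pairs(self):
        cfg = SynthesisConfig(
            seed=2, bip_coexpression_rho=0.999, n_cell_types=60,
            genes_per_chromosome=100, n_chromosomes=2, bip_fraction=0.4,
            tandem_duplicate_fraction=0.0,
        )
        ann, truth = generate_annotation(cfg)
        out = generate_expression(ann, truth, cfg)
        gm = out["gene_matrix"]
        rs = [
            stats.pearsonr(gm.loc[a], gm.loc[b]).statistic for a, b in truth.planted_bip
        ]
        assert np.mean(rs) > 0.95

    def test_mean_pair_correlation_matches_rho(self):
        cfg = SynthesisConfig(
            seed=3, bip_coexpression_rho=0.5, n_cell_types=60,
            genes_per_chromosome=500, n_chromosomes=4, bip_fraction=0.5,
            tandem_duplicate_fraction=0.0,
        )
        ann, truth = generate_annotation(cfg)
        assert len(truth.planted_bip) == 500
        gm = generate_expression(ann, truth, cfg)["gene_matrix"]
        rs = [
            stats.pearsonr(gm.loc[a], gm.loc[b]).statistic for a, b in truth.planted_bip
        ]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.05)

    def test_tau_structure(self):
        cfg = SynthesisConfig(seed=4, genes_per_chromosome=300, n_chromosomes=2)
        ann, truth = generate_annotation(cfg)
        gm = generate_expression(ann, truth, cfg)["gene_matrix"]
        taus = tau_table(gm)
        assert taus[truth.housekeeping].mean() < 0.3
        assert taus[truth.tissue_specific].mean() > 0.7
        assert (gm.to_numpy() >= 0).all()

    def test_probeset_collapse_recovers_gene_matrix(self):
        from bipscan.expression import collapse_probesets, collapse_replicates

        cfg = SynthesisConfig(seed=6, genes_per_chromosome=100, n_chromosomes=2)
        ann, truth = generate_annotation(cfg)
        out = generate_expression(ann, truth, cfg)
        collapsed = collapse_replicates(out["probeset_matrix"], out["sample_to_celltype"])
        collapsed = collapse_probesets(collapsed, out["probe_map"])
        common = collapsed.index.intersection(out["gene_matrix"].index)
        diff = (collapsed.loc[common] - out["gene_matrix"].loc[common]).to_numpy()
        assert np.abs(diff).mean() < 3.0  # replicate/probe noise only


class TestOntologyAndPathways:
    def test_dag_is_acyclic_with_three_roots(self):
        import networkx as nx

        cfg = SynthesisConfig(seed=8)
        dag = generate_ontology(cfg)
        assert nx.is_directed_acyclic_graph(dag.graph)
        assert dag.namespaces() == ["BP", "CC", "MF"]
        list(nx.topological_sort(dag.graph))  # raises on cycles

    def test_null_multiplier_false_positive_rate(self):
        """With no planted effect the enriched flag fires at ~alpha."""
        from bipscan.enrichment import enrich_all

        cfg0 = SynthesisConfig(seed=10, genes_per_chromosome=400, n_chromosomes=2, bip_fraction=0.2)
        ann, truth0 = generate_annotation(cfg0)
        universe = {g.id for g in ann.genes}
        flags = 0
        total = 0
        for seed in range(40):
            cfg = SynthesisConfig(
                seed=20_000 + seed, genes_per_chromosome=400, n_chromosomes=2,
                bip_fraction=0.2, enrichment_multiplier=1.0,
            )
            truth = type(truth0)(species="x", planted_bip=truth0.planted_bip)
            pathways = generate_pathways(ann, truth, cfg)
            res = enrich_all(pathways, truth.bip_gene_ids, universe)
            flags += sum(r.enriched for r in res)
            total += len(res)
        fpr = flags / total
        assert 0.005 <= fpr <= 0.09


class TestConservationPlanting:
    def test_full_conservation(self):
        from bipscan.conservation import classify_conservation
        from bipscan.simulate import generate_second_species

        cfg = SynthesisConfig(seed=12, conservation_fraction=1.0, genes_per_chromosome=200, n_chromosomes=2, bip_fraction=0.2)
        ann_a, truth_a = generate_annotation(cfg)
        ann_b, truth_b, orth = generate_second_species(ann_a, truth_a, cfg)
        bip_a = identify_bip(enumerate_adjacent_pairs(sort_by_tss(ann_a))).bip
        bip_b = identify_bip(enumerate_adjacent_pairs(sort_by_tss(ann_b))).bip
        calls = classify_conservation(bip_a, bip_b, orth)
        discussed = [c for c in calls if c.call != "excluded"]
        assert discussed and all(c.call == "cBIP" for c in discussed)


class TestDatasetBundle:
    def test_write_dataset_outputs_all_formats(self, tmp_path):
        cfg = SynthesisConfig(seed=14, genes_per_chromosome=60, n_chromosomes=2)
        ds = generate_dataset(cfg)
        write_dataset(ds, tmp_path)
        for name in (
            "annotation_a.tsv", "annotation_b.tsv", "truth_a.json", "orthologs.tsv",
            "proteins_a.fasta", "expression_a.tsv", "probe_map_a.tsv",
            "ontology.tsv", "go_annotations.tsv", "pathways.tsv",
        ):
            assert (tmp_path / name).exists(), name
        # the written annotation reads back identically
        from bipscan.genome import read_annotation

        back = read_annotation(tmp_path / "annotation_a.tsv", species=cfg.species)
        assert back.genes == ds.annotation.genes

    def test_octet_configs_span_conditions(self):
        cfgs = octet_configs(0)
        assert len(cfgs) == 8
        c_values = [c.c_value for c in cfgs]
        assert max(c_values) / min(c_values) > 100
        majors = [c.major_log10_mean for c in cfgs]
        assert all(m1 >= m2 for m1, m2 in zip(majors, majors[1:]))  # tracks c-value
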
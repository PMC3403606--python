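"""End-to-end orchestration of the bidirectional-promoter analysis.

The synthetic-octet pipeline mirrors the full comparative study: eight
synthetic species for the genome-scale statistics (pair classes,
distance mixture, c-value correlations, pathway enrichment) and a focal
species pair for the stages that need expression, protein, ontology and
ortholog inputs (tandem-duplicate filtering, coexpression, tau, GO
similarity, conservation).  Each stage writes a TSV report and the whole
run a machine-readable JSON twin; the per-stage counts (pairs in/out,
genes skipped) are kept in the reports so the summary numbers are
auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import conservation as cons
from . import dupfilter, enrichment, expression, gosim, mixture, pairs, simulate
from .genome import GenomeAnnotation, sort_by_tss

__all__ = ["PipelineConfig", "run_synthetic_octet", "species_pair_classes"]


@dataclass
class PipelineConfig:
    """Knobs for a full synthetic-octet run."""

    seed: int = 0
    bip_threshold: int = 1000
    h2h_mode: str = "divergent_only"
    tss_mode: str = "five_prime"
    evalue_cutoff: float = 0.01
    alpha: float = 0.05
    alternative: str = "greater"
    n_random_pairs: int = 5000
    go_aggregation: str = "max"
    genes_per_chromosome: int = 400
    synthesis_overrides: dict[str, Any] = field(default_factory=dict)


def species_pair_classes(
    annotation: GenomeAnnotation, config: PipelineConfig
) -> pairs.PairClassSet:
    """Sort, enumerate and classify adjacent pairs for one species."""
    ordered = sort_by_tss(annotation, tss_mode=config.tss_mode)
    adjacent = pairs.enumerate_adjacent_pairs(ordered, tss_mode=config.tss_mode)
    return pairs.identify_bip(
        adjacent, threshold=config.bip_threshold, h2h_mode=config.h2h_mode
    )


def _h2h_distances(pcs: pairs.PairClassSet) -> np.ndarray:
    return np.array([p.tss_distance for p in pcs.bip + pcs.rh2h], dtype=float)


def _coexpression_block(ds_expr: dict, pcs: pairs.PairClassSet, random_pairs, config):
    gm = expression.collapse_replicates(
        ds_expr["probeset_matrix"], ds_expr["sample_to_celltype"]
    )
    gm = expression.collapse_probesets(gm, ds_expr["probe_map"])
    by_class = {
        "BIP": [(p.gene_a.id, p.gene_b.id) for p in pcs.bip],
        "rH2H": [(p.gene_a.id, p.gene_b.id) for p in pcs.rh2h],
        "H2T": [(p.gene_a.id, p.gene_b.id) for p in pcs.h2t],
        "random": list(random_pairs),
    }
    table, skipped = expression.pair_coexpression(gm, by_class)
    comparisons = {}
    for a, b in [("BIP", "rH2H"), ("BIP", "H2T"), ("BIP", "random"),
                 ("rH2H", "random"), ("H2T", "random")]:
        stat, p = expression.compare_pair_classes(table, a, b, alternative=config.alternative)
        comparisons[f"{a}_vs_{b}"] = {"statistic": stat, "p_value": p}
    taus = expression.tau_table(gm)
    bip_genes = pcs.bidirectional_genes
    tau_bip = taus[taus.index.isin(bip_genes)].dropna()
    tau_other = taus[~taus.index.isin(bip_genes)].dropna()
    from .stats import wilcoxon_rank_sum

    tau_stat, tau_p = wilcoxon_rank_sum(tau_other, tau_bip, alternative="greater")
    medians = table.groupby("pair_class")["r"].median().to_dict()
    return {
        "gene_matrix": gm,
        "coexpression_table": table,
        "skipped": skipped,
        "class_median_r": medians,
        "comparisons": comparisons,
        "tau": {
            "median_bip": float(tau_bip.median()),
            "median_other": float(tau_other.median()),
            "p_other_greater_than_bip": tau_p,
            "n_bip": int(tau_bip.size),
            "n_other": int(tau_other.size),
        },
    }


def run_synthetic_octet(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every analysis stage on a seeded synthetic octet.

    Returns the report bundle as a dict; when ``outdir`` is given the
    TSV/JSON twins are written there along with the echoed config.
    """
    reports: dict[str, Any] = {"config": asdict(config)}

    # --- species set -------------------------------------------------
    octet = simulate.octet_configs(config.seed, genes_per_chromosome=config.genes_per_chromosome)
    if config.synthesis_overrides:
        octet = [
            simulate.SynthesisConfig(**{**asdict(c), **config.synthesis_overrides})
            for c in octet
        ]
    focal_cfg = octet[0]
    datasets = {}
    for i, sp_cfg in enumerate(octet):
        full = i == 0  # focal species gets expression/ontology/partner
        datasets[sp_cfg.species] = simulate.generate_dataset(
            sp_cfg,
            with_proteins=full,
            with_expression=full,
            with_ontology=full,
            with_pathways=True,
            with_partner=full,
        )

    # --- Table-1-style species summary and distance mixture ----------
    summary_rows = []
    species_stats = []
    mixture_reports = {}
    class_sets = {}
    for sp_cfg in octet:
        ds = datasets[sp_cfg.species]
        pcs = species_pair_classes(ds.annotation, config)
        class_sets[sp_cfg.species] = pcs
        n_total = len(ds.annotation)
        pct = pairs.bip_percentage(pcs.n_bidirectional_genes, n_total)
        fit = mixture.fit_two_gaussian(_h2h_distances(pcs), seed=config.seed)
        mixture_reports[sp_cfg.species] = fit.to_dict()
        summary_rows.append(
            {
                "species": sp_cfg.species,
                "n_bidirectional_promoters": pcs.n_bidirectional_promoters,
                "n_bidirectional_genes": pcs.n_bidirectional_genes,
                "n_genes_in_multiple_pairs": len(pcs.genes_in_multiple_bip_pairs()),
                "n_protein_coding_genes": n_total,
                "bip_percentage": pct,
                "c_value": sp_cfg.c_value,
            }
        )
        species_stats.append(
            mixture.SpeciesStats(
                species=sp_cfg.species,
                minor_peak_bp=fit.minor_peak_bp,
                major_peak_bp=fit.major_peak_bp,
                bip_percentage=pct,
                c_value=sp_cfg.c_value,
            )
        )
    reports["species_summary"] = summary_rows
    reports["mixture_fits"] = mixture_reports
    corr = {}
    for fld in ("major_peak", "minor_peak", "bip_percentage"):
        r, r2, p = mixture.peak_cvalue_correlation(species_stats, fld)
        corr[fld] = {"r": r, "r_squared": r2, "p_value": p}
    reports["cvalue_correlations"] = corr

    # --- focal pair: duplicate filter, coexpression, tau -------------
    focal = datasets[focal_cfg.species]
    pcs_a = class_sets[focal_cfg.species]
    pcs_b = species_pair_classes(focal.annotation_b, config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    random_a = pairs.sample_random_pairs(
        focal.annotation, n=config.n_random_pairs, seed=int(rng.integers(2**31))
    )
    random_b = pairs.sample_random_pairs(
        focal.annotation_b, n=config.n_random_pairs, seed=int(rng.integers(2**31))
    )
    pcs_a.random_pairs = random_a
    pcs_b.random_pairs = random_b
    filtered_a, removed_a = dupfilter.remove_tandem_duplicates(
        pcs_a, sequences=focal.proteins, cutoff=config.evalue_cutoff
    )
    filtered_b, removed_b = dupfilter.remove_tandem_duplicates(
        pcs_b, sequences=focal.proteins_b, cutoff=config.evalue_cutoff
    )
    reports["duplicate_filter"] = {
        "species_a": {
            "n_removed": len(removed_a),
            "pairs_in": sum(len(v) for v in pcs_a.classes().values()) + len(random_a),
            "pairs_out": sum(len(v) for v in filtered_a.classes().values())
            + len(filtered_a.random_pairs),
        },
        "species_b": {
            "n_removed": len(removed_b),
            "pairs_in": sum(len(v) for v in pcs_b.classes().values()) + len(random_b),
            "pairs_out": sum(len(v) for v in filtered_b.classes().values())
            + len(filtered_b.random_pairs),
        },
    }

    coexpr = {}
    block_a = _coexpression_block(focal.expression, filtered_a, filtered_a.random_pairs, config)
    block_b = _coexpression_block(focal.expression_b, filtered_b, filtered_b.random_pairs, config)
    for name, block in (("species_a", block_a), ("species_b", block_b)):
        coexpr[name] = {
            "class_median_r": block["class_median_r"],
            "comparisons": block["comparisons"],
            "skipped": block["skipped"],
            "tau": block["tau"],
        }
    reports["coexpression"] = coexpr

    # --- GO Resnik similarity on the focal species -------------------
    closed = gosim.extend_annotations(focal.go_direct, focal.ontology)
    go_report = {}
    for ns in gosim.NAMESPACES:
        closed_ns = closed[ns]
        ic = gosim.term_ic(closed_ns, focal.ontology, ns)
        sims_by_class: dict[str, list[float]] = {}
        pair_lists = {
            "BIP": [(p.gene_a.id, p.gene_b.id) for p in filtered_a.bip],
            "rH2H": [(p.gene_a.id, p.gene_b.id) for p in filtered_a.rh2h],
            "H2T": [(p.gene_a.id, p.gene_b.id) for p in filtered_a.h2t],
            "random": filtered_a.random_pairs[:2000],
        }
        for clazz, plist in pair_lists.items():
            sims = []
            for a, b in plist:
                s = gosim.gene_pair_resnik(
                    a, b, closed_ns, ic, dag=focal.ontology, aggregation=config.go_aggregation
                )
                if s is not None:
                    sims.append(s)
            sims_by_class[clazz] = sims
        ns_out = {"median_similarity": {k: float(np.median(v)) if v else None
                                        for k, v in sims_by_class.items()}}
        for a, b in [("BIP", "random"), ("BIP", "rH2H"), ("BIP", "H2T")]:
            stat, p = gosim.compare_similarity_classes(
                sims_by_class, a, b, alternative=config.alternative
            )
            ns_out[f"{a}_vs_{b}_p"] = p
        go_report[ns] = ns_out
    reports["go_similarity"] = go_report

    # --- per-species pathway enrichment and cross-species counts -----
    enrich_reports = {}
    per_species_results = {}
    for sp_cfg in octet:
        ds = datasets[sp_cfg.species]
        universe = {g.id for g in ds.annotation.genes}
        results = enrichment.enrich_all(
            ds.pathways,
            class_sets[sp_cfg.species].bidirectional_genes,
            universe,
            alpha=config.alpha,
        )
        per_species_results[sp_cfg.species] = results
        enrich_reports[sp_cfg.species] = {
            "n_enriched": sum(r.enriched for r in results),
            "enriched": [
                {"pathway_id": r.pathway_id, "pathway_name": r.pathway_name,
                 "p_value": r.p_value, "N0": r.N0, "N1": r.N1}
                for r in results
                if r.enriched
            ],
            "planted": list(ds.truth.planted_pathways),
        }
    reports["enrichment"] = enrich_reports
    reports["cross_species_pathway_counts"] = enrichment.cross_species_pathway_counts(
        per_species_results
    )

    # --- conservation between the focal pair -------------------------
    # classified on the unfiltered bip sets: the duplicate filter serves
    # the coexpression/cofunction analyses and would otherwise break the
    # cBIP bijection between the two species
    calls_a = cons.classify_conservation(
        pcs_a.bip, pcs_b.bip, focal.orthologs, direction="a_to_b"
    )
    calls_b = cons.classify_conservation(
        pcs_a.bip, pcs_b.bip, focal.orthologs, direction="b_to_a"
    )

    def _tally(calls):
        return {
            "cBIP": sum(c.call == "cBIP" for c in calls),
            "sBIP": sum(c.call == "sBIP" for c in calls),
            "excluded_ortholog_missing": sum(c.call == "excluded" for c in calls),
        }

    tally_a, tally_b = _tally(calls_a), _tally(calls_b)
    cbip_genes_a, sbip_genes_a = cons.split_gene_sets(calls_a)
    reports["conservation"] = {
        "species_a": tally_a,
        "species_b": tally_b,
        "n_cbip_genes_a": len(cbip_genes_a),
        "n_sbip_genes_a": len(sbip_genes_a),
        "symmetric_cbip_counts": tally_a["cBIP"] == tally_b["cBIP"],
    }
    if tally_a["cBIP"] != tally_b["cBIP"]:
        import warnings

        warnings.warn(
            "asymmetric conserved-pair counts between the species pair: "
            f"{tally_a['cBIP']} vs {tally_b['cBIP']}",
            stacklevel=2,
        )

    if outdir is not None:
        _write_reports(reports, block_a, block_b, Path(outdir))
    return reports


def _write_reports(reports: dict, block_a: dict, block_b: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "pipeline_report.json", "w") as fh:
        json.dump(reports, fh, indent=1, default=str)
    pd.DataFrame(reports["species_summary"]).to_csv(
        outdir / "species_summary.tsv", sep="\t", index=False
    )
    pd.DataFrame(reports["mixture_fits"]).T.rename_axis("species").to_csv(
        outdir / "mixture_fits.tsv", sep="\t"
    )
    block_a["coexpression_table"].to_csv(
        outdir / "coexpression_a.tsv", sep="\t", index=False
    )
    block_b["coexpression_table"].to_csv(
        outdir / "coexpression_b.tsv", sep="\t", index=False
    )
    rows = [
        {"pathway_name": name, "n_species_enriched": n}
        for name, n in reports["cross_species_pathway_counts"].items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "cross_species_counts.tsv", sep="\t", index=False)
    with open(outdir / "config_echo.json", "w") as fh:
        json.dump(reports["config"], fh, indent=1)
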
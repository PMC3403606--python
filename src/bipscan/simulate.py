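"""Synthetic genomes, expression compendia, ontologies, pathways and
ortholog maps with planted, parameterised structure.

Every pipeline input can be generated here with known truth labels, so
each analysis stage is testable end-to-end without any database
download.  The generator plants:

* per-chromosome gene layouts in which a configurable fraction of genes
  form divergent (head-to-head) pairs whose TSS gaps come from a minor
  log-normal component truncated below 1 kb, while all other intergenic
  gaps come from a major component whose location scales with genome
  size;
* tandem-duplicate adjacent pairs with near-identical protein sequences
  (and elevated coexpression);
* expression matrices in which planted divergent pairs share a target
  Pearson correlation, neighbouring genes share a weaker block-level
  correlation, and a housekeeping subset has low tissue-specificity tau;
* toy three-namespace ontologies with extra shared cellular-component
  annotations for divergent pairs;
* pathway databases with a handful of pathways overpopulated with
  bidirectional genes at a stated odds multiplier;
* a second species related through a one-to-one ortholog map in which a
  set fraction of divergent pairs is conserved intact.

One global seed fans out (via ``numpy.random.SeedSequence``) to
per-stage child seeds, so stages can be regenerated independently and
seeded runs are reproducible record for record.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .conservation import OrthologMap
from .genome import Gene, GenomeAnnotation, write_annotation_tsv
from .gosim import NAMESPACES, OntologyDAG

__all__ = [
    "SynthesisConfig",
    "TruthLabels",
    "SyntheticDataset",
    "generate_annotation",
    "generate_proteins",
    "generate_expression",
    "generate_ontology",
    "generate_go_annotations",
    "generate_pathways",
    "generate_second_species",
    "generate_dataset",
    "octet_configs",
    "write_dataset",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# SeedSequence child indices, one per generator stage
_STAGE = {
    "annotation": 0,
    "proteins": 1,
    "expression": 2,
    "ontology": 3,
    "go_annotations": 4,
    "pathways": 5,
    "second_species": 6,
}


@dataclass(frozen=True)
class SynthesisConfig:
    """Study conditions for one synthetic species.

    Fractions are in [0, 1]; correlations in (-1, 1); the minor/major
    components are the log10-bp location/spread of planted short
    (bidirectional) and long (background) intergenic TSS gaps.
    """

    seed: int = 0
    species: str = "synthA"
    c_value: float = 3.5  # haploid genome size, pg
    n_chromosomes: int = 5
    genes_per_chromosome: int = 400
    #: fraction of genes arranged in planted divergent (<1 kb) pairs
    bip_fraction: float = 0.12
    minor_log10_mean: float = math.log10(300.0)
    minor_log10_sd: float = 0.25
    major_log10_mean: float = math.log10(30000.0)
    major_log10_sd: float = 0.4
    bip_threshold: int = 1000
    gene_length_range: tuple[int, int] = (500, 5000)
    # tandem duplication
    tandem_duplicate_fraction: float = 0.03  # of adjacent pairs
    duplicate_rho: float = 0.85
    protein_length_range: tuple[int, int] = (120, 250)
    duplicate_mutation_rate: float = 0.02
    # expression
    bip_coexpression_rho: float = 0.5
    background_rho: float = 0.2
    neighbour_block_size: int = 4
    housekeeping_fraction: float = 0.4
    n_cell_types: int = 78
    n_replicates: int = 2
    max_probesets_per_gene: int = 3
    # ontology / pathways
    ontology_branching: tuple[int, int] = (5, 4)
    go_terms_per_gene: tuple[int, int] = (1, 2)
    cc_coannotation_prob: float = 0.7
    n_pathways: int = 50
    planted_enriched_pathways: int = 5
    enrichment_multiplier: float = 4.0
    pathway_size_range: tuple[int, int] = (20, 60)
    # conservation
    conservation_fraction: float = 2.0 / 3.0
    ortholog_coverage: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "bip_fraction",
            "tandem_duplicate_fraction",
            "housekeeping_fraction",
            "cc_coannotation_prob",
            "conservation_fraction",
            "ortholog_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("bip_coexpression_rho", "background_rho", "duplicate_rho"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must be in (-1, 1), got {v}")
        if self.n_cell_types < 2:
            raise ValueError("n_cell_types must be >= 2")

    def rng(self, stage: str) -> np.random.Generator:
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGE))[_STAGE[stage]]
        return np.random.default_rng(child)


@dataclass
class TruthLabels:
    """What the generator planted, keyed by gene id."""

    species: str
    planted_bip: list[tuple[str, str]] = field(default_factory=list)
    duplicates: list[tuple[str, str]] = field(default_factory=list)
    housekeeping: list[str] = field(default_factory=list)
    tissue_specific: list[str] = field(default_factory=list)
    planted_pathways: list[str] = field(default_factory=list)
    conserved_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def bip_gene_ids(self) -> set[str]:
        return {g for pair in self.planted_bip for g in pair}

    def to_dict(self) -> dict:
        return asdict(self)


def _layout_chromosome(
    units: list[tuple],
    chrom: str,
    config: SynthesisConfig,
    rng: np.random.Generator,
) -> list[Gene]:
    """Place a unit list (pairs and singles) left to right on one chromosome.

    Gene bodies never overlap and TSSs strictly increase along the
    layout, so adjacency in TSS order equals layout order.  Inter-unit
    gaps come from the major component; within planted divergent pairs
    the TSS gap comes from the minor component truncated below the bip
    threshold.
    """
    lo, hi = config.gene_length_range
    genes: list[Gene] = []
    pos = 1

    def gene_len() -> int:
        return int(rng.integers(lo, hi + 1))

    def major_gap() -> int:
        return max(1, round(10 ** rng.normal(config.major_log10_mean, config.major_log10_sd)))

    def minor_gap() -> int:
        while True:
            d = round(10 ** rng.normal(config.minor_log10_mean, config.minor_log10_sd))
            if 1 <= d < config.bip_threshold:
                return int(d)

    for unit in units:
        pos += major_gap()
        if unit[0] == "pair":
            id_a, id_b = unit[1]
            len_a, len_b = gene_len(), gene_len()
            # divergent arrangement: '-' gene first, its TSS at the right
            # end of its body; the '+' partner starts a minor-gap away
            genes.append(Gene(id_a, chrom, "-", pos, pos + len_a))
            tss_a = pos + len_a
            start_b = tss_a + minor_gap()
            genes.append(Gene(id_b, chrom, "+", start_b, start_b + len_b))
            pos = start_b + len_b + 1
        else:
            gid = unit[1]
            length = gene_len()
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gid, chrom, strand, pos, pos + length))
            pos = pos + length + 1
    return genes


def generate_annotation(
    config: SynthesisConfig, id_prefix: str | None = None
) -> tuple[GenomeAnnotation, TruthLabels]:
    """Synthetic gene layout with planted divergent pairs and duplicates."""
    rng = config.rng("annotation")
    prefix = id_prefix if id_prefix is not None else f"{config.species}_G"
    truth = TruthLabels(species=config.species)
    genes: list[Gene] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:05d}"

    for c in range(config.n_chromosomes):
        n_genes = config.genes_per_chromosome
        n_pairs = int(round(config.bip_fraction * n_genes / 2))
        n_singles = n_genes - 2 * n_pairs
        units: list[tuple] = [("pair", (new_id(), new_id())) for _ in range(n_pairs)]
        units += [("single", new_id()) for _ in range(n_singles)]
        rng.shuffle(units)
        chrom_genes = _layout_chromosome(units, f"chr{c + 1}", config, rng)
        genes.extend(chrom_genes)
        truth.planted_bip.extend(u[1] for u in units if u[0] == "pair")

    annotation = GenomeAnnotation(species=config.species, genes=genes, c_value=config.c_value)

    # tandem duplicates: adjacent (layout-order) pairs, no gene in two
    # duplicate pairs; a candidate either is a planted divergent pair or
    # touches no planted pair at all
    bip_genes = truth.bip_gene_ids
    bip_keys = {frozenset(p) for p in truth.planted_bip}
    adjacent: list[tuple[str, str]] = []
    idx = 0
    for _ in range(config.n_chromosomes):
        chrom_slice = genes[idx : idx + config.genes_per_chromosome]
        adjacent.extend(
            (a.id, b.id) for a, b in zip(chrom_slice, chrom_slice[1:])
        )
        idx += config.genes_per_chromosome
    candidates = [
        p
        for p in adjacent
        if frozenset(p) in bip_keys or (p[0] not in bip_genes and p[1] not in bip_genes)
    ]
    n_dup = int(round(config.tandem_duplicate_fraction * len(adjacent)))
    rng.shuffle(candidates)
    used: set[str] = set()
    for a, b in candidates:
        if len(truth.duplicates) >= n_dup:
            break
        if a in used or b in used:
            continue
        truth.duplicates.append((a, b))
        used.update((a, b))
    return annotation, truth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    hits = rng.random(chars.size) < rate
    chars[hits] = rng.choice(_AA, size=int(hits.sum()))
    return "".join(chars)


def generate_proteins(
    annotation: GenomeAnnotation, truth: TruthLabels, config: SynthesisConfig
) -> dict[str, str]:
    """One protein per gene; duplicate partners are near-identical copies."""
    rng = config.rng("proteins")
    lo, hi = config.protein_length_range
    dup_partner = {a: b for a, b in truth.duplicates}
    proteins: dict[str, str] = {}
    for g in annotation.genes:
        if g.id in proteins:
            continue
        seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        proteins[g.id] = seq
        partner = dup_partner.get(g.id)
        if partner is not None:
            proteins[partner] = _mutate(seq, config.duplicate_mutation_rate, rng)
    return proteins


def generate_expression(
    annotation: GenomeAnnotation, truth: TruthLabels, config: SynthesisConfig
) -> dict:
    """Probeset-level expression with planted correlation and tau structure.

    Planted divergent pairs (and duplicate pairs, more strongly) share a
    pair-level latent factor; other genes share a weaker block-level
    factor with their immediate neighbours, emulating chromatin-domain
    coexpression.  Genes of planted divergent pairs are housekeeping-like
    (flat cell-type means, so their sample Pearson r matches the planted
    rho); remaining genes are housekeeping with probability
    ``housekeeping_fraction`` and single-dominant-tissue specific
    otherwise.  Values are non-negative.

    Returns a dict with keys ``gene_matrix`` (genes x cell types),
    ``probeset_matrix`` (probesets x replicate arrays), ``probe_map``
    (probeset -> gene) and ``sample_to_celltype``.
    """
    rng = config.rng("expression")
    n_ct = config.n_cell_types
    gene_ids = [g.id for g in annotation.genes]
    order = {gid: i for i, gid in enumerate(gene_ids)}

    rho_pairs: dict[str, tuple[int, float]] = {}  # gene -> (latent index, rho)
    latents: list[np.ndarray] = []

    def add_pair(a: str, b: str, rho: float) -> None:
        latents.append(rng.standard_normal(n_ct))
        rho_pairs[a] = rho_pairs[b] = (len(latents) - 1, rho)

    for a, b in truth.planted_bip:
        add_pair(a, b, config.bip_coexpression_rho)
    for a, b in truth.duplicates:
        add_pair(a, b, config.duplicate_rho)  # overrides the bip latent if shared

    # block latents for everyone else: consecutive unpaired genes
    unpaired = [gid for gid in gene_ids if gid not in rho_pairs]
    for i in range(0, len(unpaired), config.neighbour_block_size):
        latents.append(rng.standard_normal(n_ct))
        for gid in unpaired[i : i + config.neighbour_block_size]:
            rho_pairs[gid] = (len(latents) - 1, config.background_rho)

    paired_genes = truth.bip_gene_ids | {g for d in truth.duplicates for g in d}
    values = np.empty((len(gene_ids), n_ct))
    for gid in gene_ids:
        li, rho = rho_pairs[gid]
        z = math.sqrt(rho) * latents[li] + math.sqrt(1.0 - rho) * rng.standard_normal(n_ct)
        if gid in paired_genes or rng.random() < config.housekeeping_fraction:
            m = rng.uniform(100.0, 300.0)
            profile = m + 0.15 * m * z
            truth.housekeeping.append(gid)
        else:
            amp = rng.uniform(200.0, 600.0)
            profile = 0.2 * amp + 0.15 * amp * z
            profile[int(rng.integers(n_ct))] += amp
            truth.tissue_specific.append(gid)
        values[order[gid]] = np.maximum(profile, 0.0)

    celltypes = [f"ct{i:03d}" for i in range(n_ct)]
    gene_matrix = pd.DataFrame(values, index=gene_ids, columns=celltypes)

    # probesets x replicate arrays, with measurement noise
    probe_map: dict[str, str] = {}
    rows = []
    for gid in gene_ids:
        for j in range(int(rng.integers(1, config.max_probesets_per_gene + 1))):
            probe_map[f"PS_{gid}_{j}"] = gid
            rows.append((f"PS_{gid}_{j}", gid))
    samples = [f"{ct}_r{j}" for ct in celltypes for j in range(config.n_replicates)]
    sample_to_celltype = {s: s.rsplit("_r", 1)[0] for s in samples}
    probe_values = np.empty((len(rows), len(samples)))
    for i, (_, gid) in enumerate(rows):
        base = np.repeat(gene_matrix.loc[gid].to_numpy(), config.n_replicates)
        probe_values[i] = np.maximum(base + rng.normal(0.0, 3.0, size=base.size), 0.0)
    probeset_matrix = pd.DataFrame(probe_values, index=[r[0] for r in rows], columns=samples)

    return {
        "gene_matrix": gene_matrix,
        "probeset_matrix": probeset_matrix,
        "probe_map": probe_map,
        "sample_to_celltype": sample_to_celltype,
    }


def generate_ontology(config: SynthesisConfig) -> OntologyDAG:
    """Toy three-namespace is_a DAG: root, a middle tier, and leaves.

    A few leaves get a second parent so the graph is a genuine DAG, not
    a tree.
    """
    rng = config.rng("ontology")
    g = nx.DiGraph()
    n_mid, n_leaf_each = config.ontology_branching
    for ns in NAMESPACES:
        root = f"{ns}:0000"
        g.add_node(root, namespace=ns)
        mids = []
        k = 1
        for _ in range(n_mid):
            mid = f"{ns}:{k:04d}"
            k += 1
            g.add_node(mid, namespace=ns)
            g.add_edge(mid, root)
            mids.append(mid)
        for mid in mids:
            for _ in range(n_leaf_each):
                leaf = f"{ns}:{k:04d}"
                k += 1
                g.add_node(leaf, namespace=ns)
                g.add_edge(leaf, mid)
                if rng.random() < 0.15:
                    other = mids[int(rng.integers(len(mids)))]
                    if other != mid:
                        g.add_edge(leaf, other)
    return OntologyDAG(g)


def _leaves(dag: OntologyDAG, ns: str) -> list[str]:
    return sorted(
        n
        for n, d in dag.graph.nodes(data=True)
        if d.get("namespace") == ns and dag.graph.in_degree(n) == 0
    )


def generate_go_annotations(
    annotation: GenomeAnnotation,
    truth: TruthLabels,
    dag: OntologyDAG,
    config: SynthesisConfig,
) -> dict[str, set[str]]:
    """Direct gene->term annotations; planted divergent pairs co-annotate
    a shared cellular-component leaf with probability
    ``cc_coannotation_prob`` (the CC-only similarity elevation)."""
    rng = config.rng("go_annotations")
    leaves = {ns: _leaves(dag, ns) for ns in NAMESPACES}
    lo, hi = config.go_terms_per_gene
    direct: dict[str, set[str]] = {}
    for g in annotation.genes:
        terms = set()
        for ns in NAMESPACES:
            n_terms = int(rng.integers(lo, hi + 1))
            terms.update(rng.choice(leaves[ns], size=n_terms, replace=False))
        direct[g.id] = terms
    for a, b in truth.planted_bip:
        if rng.random() < config.cc_coannotation_prob:
            shared = str(rng.choice(leaves["CC"]))
            direct[a].add(shared)
            direct[b].add(shared)
    return direct


def generate_pathways(
    annotation: GenomeAnnotation, truth: TruthLabels, config: SynthesisConfig
) -> dict[str, tuple[str, set[str]]]:
    """Pathway db; the first ``planted_enriched_pathways`` pathways draw
    bidirectional genes at ``enrichment_multiplier`` times the odds of
    other genes.  Pathway *names* are shared across species so that
    cross-species enrichment counts line up."""
    rng = config.rng("pathways")
    gene_ids = np.array([g.id for g in annotation.genes])
    bip = truth.bip_gene_ids
    weights_enriched = np.array(
        [config.enrichment_multiplier if g in bip else 1.0 for g in gene_ids]
    )
    lo, hi = config.pathway_size_range
    pathways: dict[str, tuple[str, set[str]]] = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        name = f"pathway_{i:03d}"
        pid = f"{config.species}_PW{i:03d}"
        if i < config.planted_enriched_pathways:
            p = weights_enriched / weights_enriched.sum()
            members = rng.choice(gene_ids, size=size, replace=False, p=p)
            truth.planted_pathways.append(pid)
        else:
            members = rng.choice(gene_ids, size=size, replace=False)
        pathways[pid] = (name, set(members))
    return pathways


def generate_second_species(
    annotation_a: GenomeAnnotation,
    truth_a: TruthLabels,
    config: SynthesisConfig,
    species_b: str = "synthB",
    c_value_b: float | None = None,
) -> tuple[GenomeAnnotation, TruthLabels, OrthologMap]:
    """A partner genome linked by a strictly one-to-one ortholog map.

    ``conservation_fraction`` of species-A divergent pairs are laid out
    as divergent (<1 kb) pairs in B through their orthologs; the
    orthologs of the remaining pair genes are scattered as singletons.
    B also carries its own planted divergent pairs (one per
    non-conserved A pair) so both species have species-specific pairs.
    Non-pair A genes receive orthologs with probability
    ``ortholog_coverage``.
    """
    rng = config.rng("second_species")
    prefix = f"{species_b}_G"
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:05d}"

    ortho_pairs: list[tuple[str, str]] = []
    truth_b = TruthLabels(species=species_b)
    units: list[tuple] = []
    n_broken = 0

    bip_genes_a = truth_a.bip_gene_ids
    for a, b in truth_a.planted_bip:
        oa, ob = new_id(), new_id()
        ortho_pairs.extend([(a, oa), (b, ob)])
        if rng.random() < config.conservation_fraction:
            units.append(("pair", (oa, ob)))
            truth_b.planted_bip.append((oa, ob))
            truth_a.conserved_pairs.append((a, b))
            truth_b.conserved_pairs.append((oa, ob))
        else:
            units.extend([("single", oa), ("single", ob)])
            n_broken += 1

    # orthologs of non-pair A genes; some are recombined into B-own
    # divergent pairs (species-specific from B's point of view: their A
    # orthologs exist but are not bidirectionally arranged there)
    loose: list[str] = []
    for g in annotation_a.genes:
        if g.id in bip_genes_a:
            continue
        if rng.random() < config.ortholog_coverage:
            og = new_id()
            ortho_pairs.append((g.id, og))
            loose.append(og)
    rng.shuffle(loose)
    for _ in range(n_broken):
        if len(loose) < 2:
            break
        pa, pb = loose.pop(), loose.pop()
        units.append(("pair", (pa, pb)))
        truth_b.planted_bip.append((pa, pb))
    units.extend(("single", og) for og in loose)

    rng.shuffle(units)
    genes: list[Gene] = []
    n_chrom = config.n_chromosomes
    per_chrom = math.ceil(len(units) / n_chrom)
    for c in range(n_chrom):
        chunk = units[c * per_chrom : (c + 1) * per_chrom]
        genes.extend(_layout_chromosome(chunk, f"chr{c + 1}", config, rng))
    annotation_b = GenomeAnnotation(
        species=species_b,
        genes=genes,
        c_value=c_value_b if c_value_b is not None else annotation_a.c_value,
    )
    return annotation_b, truth_b, OrthologMap(ortho_pairs)


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes for a focal species pair."""

    config: SynthesisConfig
    annotation: GenomeAnnotation
    truth: TruthLabels
    proteins: dict[str, str] | None = None
    expression: dict | None = None
    ontology: OntologyDAG | None = None
    go_direct: dict[str, set[str]] | None = None
    pathways: dict[str, tuple[str, set[str]]] | None = None
    annotation_b: GenomeAnnotation | None = None
    truth_b: TruthLabels | None = None
    orthologs: OrthologMap | None = None
    proteins_b: dict[str, str] | None = None
    expression_b: dict | None = None


def generate_dataset(
    config: SynthesisConfig,
    with_proteins: bool = True,
    with_expression: bool = True,
    with_ontology: bool = True,
    with_pathways: bool = True,
    with_partner: bool = True,
) -> SyntheticDataset:
    """Generate the full input bundle for one focal species (plus partner)."""
    annotation, truth = generate_annotation(config)
    ds = SyntheticDataset(config=config, annotation=annotation, truth=truth)
    if with_partner:
        ds.annotation_b, ds.truth_b, ds.orthologs = generate_second_species(
            annotation, truth, config
        )
    if with_proteins:
        ds.proteins = generate_proteins(annotation, truth, config)
        if with_partner:
            ds.proteins_b = generate_proteins(ds.annotation_b, ds.truth_b, config)
    if with_expression:
        ds.expression = generate_expression(annotation, truth, config)
        if with_partner:
            ds.expression_b = generate_expression(ds.annotation_b, ds.truth_b, config)
    if with_ontology:
        ds.ontology = generate_ontology(config)
        ds.go_direct = generate_go_annotations(annotation, truth, ds.ontology, config)
    if with_pathways:
        ds.pathways = generate_pathways(annotation, truth, config)
    return ds


#: Synthetic octet: (species tag, c-value pg, planted bip gene fraction).
#: c-values span the invertebrate-to-mammal range; the planted fraction
#: of bidirectionally arranged genes falls with genome size and the
#: major intergenic peak grows linearly with it.
OCTET_SPECIES: tuple[tuple[str, float, float], ...] = (
    ("synth_hs", 3.5, 0.11),
    ("synth_mm", 3.3, 0.115),
    ("synth_rn", 3.0, 0.06),
    ("synth_bt", 2.9, 0.06),
    ("synth_gg", 1.25, 0.09),
    ("synth_dm", 0.18, 0.32),
    ("synth_ce", 0.10, 0.18),
    ("synth_sc", 0.02, 0.51),
)


def octet_configs(seed: int, genes_per_chromosome: int = 400) -> list[SynthesisConfig]:
    """Configs for eight synthetic species with c-value-linked structure."""
    configs = []
    for i, (name, c_value, bip_fraction) in enumerate(OCTET_SPECIES):
        major_bp = 2000.0 + 8000.0 * c_value
        configs.append(
            SynthesisConfig(
                seed=seed + i,
                species=name,
                c_value=c_value,
                bip_fraction=bip_fraction,
                major_log10_mean=math.log10(major_bp),
                major_log10_sd=0.3,
                genes_per_chromosome=genes_per_chromosome,
            )
        )
    return configs


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every standard input format the pipeline reads, plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotation_tsv(ds.annotation, outdir / "annotation_a.tsv")
    with open(outdir / "truth_a.json", "w") as fh:
        json.dump(ds.truth.to_dict(), fh, indent=1)
    if ds.annotation_b is not None:
        write_annotation_tsv(ds.annotation_b, outdir / "annotation_b.tsv")
        with open(outdir / "truth_b.json", "w") as fh:
            json.dump(ds.truth_b.to_dict(), fh, indent=1)
    if ds.orthologs is not None:
        with open(outdir / "orthologs.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in ds.orthologs.a_to_b.items():
                fh.write(f"{a}\t{b}\n")
    for name, proteins in (("a", ds.proteins), ("b", ds.proteins_b)):
        if proteins:
            with open(outdir / f"proteins_{name}.fasta", "w") as fh:
                for gid, seq in proteins.items():
                    fh.write(f">{gid}\n{seq}\n")
    for tag, expr in (("a", ds.expression), ("b", ds.expression_b)):
        if expr is not None:
            expr["probeset_matrix"].to_csv(outdir / f"expression_{tag}.tsv", sep="\t")
            pd.Series(expr["probe_map"], name="gene_id").rename_axis(
                "probeset_id"
            ).to_csv(outdir / f"probe_map_{tag}.tsv", sep="\t")
    if ds.ontology is not None:
        with open(outdir / "ontology.tsv", "w") as fh:
            fh.write("child\tparent\tnamespace\n")
            for ns in ds.ontology.namespaces():
                fh.write(f"{ds.ontology.root(ns)}\t\t{ns}\n")
            for child, parent in ds.ontology.graph.edges():
                ns = ds.ontology.namespace_of(child)
                fh.write(f"{child}\t{parent}\t{ns}\n")
    if ds.go_direct is not None:
        with open(outdir / "go_annotations.tsv", "w") as fh:
            fh.write("gene_id\tterm_id\n")
            for gid, terms in ds.go_direct.items():
                for t in sorted(terms):
                    fh.write(f"{gid}\t{t}\n")
    if ds.pathways is not None:
        with open(outdir / "pathways.tsv", "w") as fh:
            fh.write("pathway_id\tpathway_name\tgene_id\n")
            for pid, (name, members) in ds.pathways.items():
                for g in sorted(members):
                    fh.write(f"{pid}\t{name}\t{g}\n")
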
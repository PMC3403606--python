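# Methods

## Scope and model

The package analyses the architecture of *bidirectional promoters*:
adjacent genes on opposite strands transcribed away from each other
(head-to-head, H2H) whose transcription start sites (TSSs) are less than
1 kb apart. Such a pair (BIP) shares one intergenic regulatory region.
The analysis chain compares BIP pairs against remote head-to-head pairs
(rH2H, divergent but ≥ 1 kb), head-to-tail neighbours (H2T, same
strand), convergent neighbours (T2T) and random gene pairs, in terms of
intergenic distance structure, coexpression, tissue specificity,
functional (GO) similarity, pathway enrichment and cross-species
conservation.

## Coordinates and TSS derivation

Coordinates are 1-based inclusive (the GFF3 dialect). The TSS of a gene
is its 5' end: `start` on the plus strand, `end` on the minus strand.
Because some annotation exports report a strand-agnostic "gene start",
`tss_mode="lower_coordinate"` reproduces that reading; the default is
the biologically correct 5' end. Genes are sorted per chromosome by
(TSS, start, id) — the tie-break is deterministic and arbitrary.
Mitochondrial chromosomes and unplaced fragments are dropped at load
time (configurable exclusion list); the biotype filter defaults to
protein-coding genes only. Overlapping neighbours are kept; the TSS
distance is always |ΔTSS| ≥ 0.

Opposite-strand neighbours are split into divergent (H2H) and convergent
(T2T); only divergent pairs enter bip calling by default, since only
they can share an upstream regulatory region. `h2h_mode="all_opposite"`
lumps both, for comparison with analyses that did not make the
distinction. The bip threshold is strict (`distance < 1000`).

## Distance mixture

TSS distances between H2H pairs span several orders of magnitude, so the
two-component Gaussian mixture is fitted to log10(distance) by
expectation-maximisation (raw-scale fitting is available). Zero
distances are mapped to 1 bp before the transform. Initialisation is
k-means (2 clusters, fixed seed); component variances are floored at
(10⁻³)² to prevent degenerate spikes; the log-likelihood is asserted
non-decreasing at every iteration and convergence is declared at a
relative tolerance of 10⁻⁸ (500 iteration cap; a non-converged fit is
returned flagged, not raised). Components are reported minor-mean-first
and peak locations as 10^mean bp. KDE smoothing uses a Gaussian kernel
with Silverman's rule by default; a numeric bandwidth must be supplied
for zero-variance samples, where the density is the kernel itself.

Per-species minor/major peaks and bidirectional-gene percentages are
correlated against haploid genome size (c-value, pg) with two-sided
Pearson tests.

## Tandem-duplicate filter

Adjacent paralogues from local duplication share sequence, expression
and function and would confound every neighbouring-pair comparison. Each
pair is scored by Smith–Waterman local alignment of the partner proteins
(BLOSUM62, gap open 11, extend 1, via Biopython's PairwiseAligner) and
the optimal score S converted to an e-value E = K·m·n·e^(−λS). The
constants (λ = 0.2188, K = 0.0242) were calibrated by maximum-likelihood
Gumbel fitting on 6000 optimal local scores of random uniform-composition
protein pairs (lengths 120–250), so that P(E < e) ≈ e for unrelated
sequences under this scoring; published ungapped BLOSUM62 constants can
be substituted when gap penalties are set prohibitive. When S ≤ 0 no
local alignment exists and E is reported as infinity. Pairs with
E < 0.01 are removed from **all** classes, including the random control
pairs (the choice is uniform because any class feeds the downstream
comparisons). Note a calibrated E < 0.01 rule removes ~1% of unrelated
pairs by construction; true duplicates sit at E < 10⁻³⁰, dozens of
orders of magnitude away. Pairs without resolvable sequences pass
through with a warning. An external e-value table (e.g. from BLAST) can
replace the internal alignment for exact reproduction of a published
filter.

## Expression statistics

Replicate arrays of a cell type are averaged first (`replicate_collapse
= mean`; the synthetic compendium has 2 replicates × 78 cell types,
mirroring a 156-array/78-cell-type microarray design); genes measured by
several probesets take the arithmetic mean of their probeset rows.
Coexpression of a pair is the Pearson correlation of the two gene
profiles; pairs with a missing or constant profile are skipped and
counted. Tissue specificity is τ = Σᵢ(1 − Eᵢ/E_max)/(n − 1) ∈ [0, 1]
(0 = uniform/housekeeping, 1 = single-tissue); τ is undefined for
all-zero profiles and invariant under positive rescaling.

Class contrasts use the Wilcoxon rank-sum test: exact enumeration for
small tie-free samples, otherwise the tie-corrected normal
approximation. Because the scientific claims are directional
("higher coexpression", "lower specificity"), the default alternative is
one-sided `greater`; two-sided testing is a flag away.

## GO Resnik similarity

Direct gene→term annotations are closed over is_a ancestry per namespace
(BP/MF/CC; part_of edges are out of scope). The information content of a
term is −ln of the fraction of namespace-annotated genes whose closure
contains it, normalised **per namespace**, so each namespace root has
ic = 0 exactly. Pair similarity aggregates the most informative common
ancestor (MICA) over cross term pairs; the default is the maximum (for
closed sets this is simply the highest-ic shared term), with
best-match-average over direct annotations as an alternative. Natural
log is used throughout; any fixed base only rescales and leaves rank
tests unchanged.

## Pathway enrichment

For a pathway with N1 genes in a universe of N protein-coding genes, of
which N2 are bidirectional and N0 bidirectional-in-pathway, the
enrichment p-value is the hypergeometric upper tail P(X ≥ N0), computed
as a log-space sum of pmf terms (gammaln + logsumexp) for numerical
stability. The universe is all protein-coding genes of the species, not
only pathway-annotated ones. Enrichment is called at raw p < 0.05 with
no multiple-testing correction — deliberately matching the analysed
protocol — and a Benjamini–Hochberg option is provided off by default.
Cross-species comparison counts, per shared pathway name, the species in
which it is enriched.

## Conservation

A bidirectional pair in species A is conserved (cBIP) iff both genes
have one-to-one orthologs in species B **and** those orthologs are
partners of a single bidirectional pair in B; pairs lacking an ortholog
are excluded from the discussed universe with an explicit reason code,
and remaining pairs are species-specific (sBIP). On a fixed pair of bip
sets the conserved pairs of the two species are in bijection through the
ortholog map, so the two cBIP counts must agree; the pipeline asserts
this and warns on any asymmetry. The duplicate filter is *not* applied
before conservation classification — it serves the
coexpression/cofunction contrasts and would otherwise break the
bijection.

## Synthetic-data generator

The generator plants every effect the pipeline measures, with truth
labels, under one global seed fanned out to per-stage child seeds
(`numpy.random.SeedSequence`), so stages regenerate independently and
runs are bit-reproducible.

* **Layout.** Each chromosome is a shuffled sequence of units — planted
  divergent pairs and singletons — separated by gaps drawn from the
  major log-normal component (default log10-mean log10(30000), sd 0.4).
  Within a planted pair the TSS gap comes from the minor component
  (log10-mean log10(300), sd 0.25) truncated below 1 kb. Gene bodies
  never overlap and TSSs increase along the layout, so adjacency in TSS
  order equals layout order. For compact genomes whose major component
  has real mass below 1 kb, extra sub-kilobase divergent pairs arise
  beyond the truth labels; they are genuine bidirectional pairs under
  the definition, and tests bound them by the component's tail mass.
* **Octet.** Eight synthetic species span c-values 0.02–3.5 pg with the
  major peak placed at 2000 + 8000·c bp (linear in genome size) and
  planted bidirectional-gene fractions 0.06–0.51 falling with genome
  size, reproducing the qualitative comparative picture (stable
  sub-kilobase minor peak, major peak and percentage correlated with
  c-value).
* **Duplicates.** A set fraction of adjacent pairs get near-identical
  proteins (2% point substitutions on a shared random sequence) and
  elevated expression correlation (ρ = 0.85); other proteins are
  independent uniform-composition sequences.
* **Expression.** Planted bip genes are housekeeping-like: flat
  cell-type means (uniform 100–300) with 15% proportional noise shared
  through a pair latent factor at the target ρ (default 0.5). This
  encodes two planted facts at once — bidirectional genes have low τ
  (≈ 0.26), and the sample Pearson r of a planted pair is an unbiased
  estimate of ρ (no mean-profile variance dilutes it). Other genes sit
  in blocks of four consecutive neighbours sharing a weaker latent
  (ρ = 0.2, the chromatin-domain effect) and are housekeeping with
  probability 0.4, otherwise single-dominant-tissue specific (τ ≈ 0.8).
  Values are clipped at zero; probeset and replicate layers add small
  Gaussian measurement noise.
* **Ontology/pathways.** A toy three-namespace is_a DAG (root, 5 mid
  terms, 20 leaves each, occasional second parents); planted bip pairs
  co-annotate a shared CC leaf with probability 0.7 (the CC-only
  similarity elevation). Five of fifty pathways draw bidirectional genes
  at 4× the odds of other genes; pathway *names* are shared across
  species so cross-species counts line up.
* **Conservation.** Two thirds of planted pairs (the fraction observed
  in comparative data: 540 conserved of 810 discussed pairs) are laid
  out intact in the partner genome via fresh ortholog ids; the rest are
  scattered as singletons, and an equal number of partner-own divergent
  pairs are built from orthologs of non-pair genes so both species have
  species-specific pairs inside the discussed universe. Non-pair genes
  receive orthologs with probability 0.8.

**What the generator does not emulate:** realistic sequence evolution,
microarray noise beyond Gaussian layers, gene-density heterogeneity
along chromosomes, overlapping or nested genes, many-to-many homology,
and ontology/pathway structure at realistic scale. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted effects, not biological conclusions about real
genomes.

## Problem sizes and defaults

Default study conditions: 8 species × 5 chromosomes × 400 genes (2000
genes/species), 78 cell types × 2 replicates, 50 pathways (5 planted
enriched), 5000 random control pairs per focal species, mixture fits on
all H2H distances per species, enrichment calibration over 100
planted-effect and 200 null regenerations of the pathway database on a
fixed genome. A full octet pipeline run completes in well under a minute
on one CPU; the test suite in about half a minute.

## Known limitations

* The EM fit can misweight heavily imbalanced mixtures when the
  components overlap; in the planted conditions the components are
  separated by ~2 log10 units and recovery is tight (|Δμ| ≤ 0.05).
* Karlin–Altschul constants are calibrated for the default scoring and
  uniform residue composition; strongly biased compositions would need
  recalibration (or an external e-value table).
* The hypergeometric rule follows the analysed protocol: raw p < 0.05,
  no correction. Interpret per-pathway flags accordingly or enable the
  BH option.
* Random control pairs are drawn genome-wide (not within-chromosome),
  so they do not control for chromosome-scale expression territory
  effects.
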
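# bipscan

Comparative analysis of **bidirectional promoter architecture**: divergent
(head-to-head) gene pairs whose transcription start sites lie less than
1 kb apart, sharing a single intergenic regulatory region.

The package implements the full analysis chain used in comparative studies
of this arrangement, for researchers in regulatory genomics who want to
reproduce, extend or stress-test it without database downloads:

1. **Pair identification** — parse gene annotations (GFF3 or TSV), derive
   strand-aware TSSs, sort per chromosome, classify adjacent pairs as
   head-to-head (H2H, divergent), tail-to-tail (T2T, convergent) or
   head-to-tail (H2T, same strand), and call bidirectional pairs (BIP) at
   TSS distance < 1 kb; remaining H2H pairs are "remote" (rH2H).
2. **Distance mixture** — KDE smoothing and a two-component Gaussian
   mixture fitted by EM to log10 TSS distances, giving the minor
   (sub-kilobase, bidirectional) and major (genome-size-linked) peaks,
   and Pearson correlations of peaks and bidirectional-gene percentages
   against genome c-values.
3. **Tandem-duplicate filtering** — Smith–Waterman protein alignment
   (BLOSUM62, affine gaps) with Karlin–Altschul e-values,
   E = K·m·n·e^(−λS); pairs with E < 0.01 are removed before any
   coexpression/cofunction comparison.
4. **Expression** — probeset → gene collapse (mean), replicate-array
   averaging, per-pair Pearson coexpression, the tissue-specificity index
   τ = Σᵢ(1 − Eᵢ/E_max)/(n − 1), and Wilcoxon rank-sum contrasts between
   pair classes.
5. **GO semantics** — Resnik similarity: annotation closure over the is_a
   DAG, per-namespace information content ic(t) = −ln p(t), and the most
   informative common ancestor aggregated over term pairs.
6. **Pathway enrichment** — hypergeometric upper tail
   P = 1 − Σ_{i<N0} C(N1,i)·C(N−N1,N2−i)/C(N,N2) for a universe of N
   protein-coding genes, N1 in the pathway, N2 bidirectional, N0 observed
   inside; enriched at raw p < 0.05.
7. **Conservation** — bidirectional pairs whose one-to-one orthologs form
   a bidirectional pair in a second species are conserved (cBIP), the
   rest species-specific (sBIP).
8. **Synthetic data** — a seeded generator that plants every one of these
   effects (pair layout, duplicate sequences, coexpression, τ structure,
   CC co-annotation, pathway enrichment, conservation fraction) with
   truth labels, so every stage is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
octet of species (run them in order; outputs land in `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_identify_pairs.py
python analysis/03_distance_mixture.py
```

`02_identify_pairs.py` prints a per-species summary (excerpt):

```
 species  n_bidirectional_promoters  n_bidirectional_genes  n_protein_coding_genes  bip_percentage
synth_dm                        330                    660                    2000            33.0
synth_ce                        206                    412                    2000            20.6
synth_sc                        522                   1044                    2000            52.2
```

Each species has 2000 genes; the bidirectional percentage is
100 × (bidirectional genes)/(all protein-coding genes) and rises as the
planted genome size falls. `03_distance_mixture.py` then reports the
fitted peaks and their c-value correlations:

```
synth_sc: minor peak   287.4 bp, major peak    1995.2 bp

major peak vs c-value: r^2 = 0.9977 (p = 3.8e-09)
minor peak vs c-value: p = 0.733 (no correlation expected)
percentage vs c-value: r = -0.758 (negative, as planted)
```

The minor peak stays sub-kilobase in every genome while the major peak
tracks genome size — the signature that motivates the fixed < 1 kb
definition of a bidirectional promoter. Continuing with
`04`–`08` filters duplicates, contrasts coexpression and τ by pair class
(`species a: median r BIP 0.50 | rH2H 0.10 | H2T 0.09 | random -0.00`),
shows the CC-only elevation of GO similarity, recovers the five planted
pathways in the cross-species enrichment counts, and classifies
conserved pairs (`74 cBIP, 36 sBIP, conserved fraction 0.673`, identical
in both directions as the ortholog bijection requires).

The same stages are available programmatically
(`bipscan.run_synthetic_octet`) and through the `bipscan` CLI
(`simulate`, `pairs`, `fit`, `run`).

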
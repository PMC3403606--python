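"""Classify adjacent gene pairs in all eight species, call bidirectional
pairs (TSS distance < 1 kb, divergent orientation), and write the
species summary plus per-species pair tables and the focal random-pair
control sample."""

import csv
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, FOCAL, RESULTS, SEED, species_meta_path

import pandas as pd

from bipscan.genome import read_annotation, sort_by_tss
from bipscan.pairs import (
    bip_percentage,
    enumerate_adjacent_pairs,
    identify_bip,
    sample_random_pairs,
    write_pair_table,
)


def classify(path, species):
    ann = read_annotation(path, species=species)
    pcs = identify_bip(enumerate_adjacent_pairs(sort_by_tss(ann)))
    return ann, pcs


def main() -> None:
    meta = pd.read_csv(species_meta_path(), sep="\t")
    rows = []
    for species in meta["species"]:
        sp_dir = DATA / species
        ann, pcs = classify(sp_dir / "annotation_a.tsv", species)
        write_pair_table(pcs.bip + pcs.rh2h + pcs.h2t + pcs.t2t, sp_dir / "pairs_a.tsv")
        rows.append(
            {
                "species": species,
                "n_bidirectional_promoters": pcs.n_bidirectional_promoters,
                "n_bidirectional_genes": pcs.n_bidirectional_genes,
                "n_protein_coding_genes": len(ann),
                "bip_percentage": bip_percentage(pcs.n_bidirectional_genes, len(ann)),
            }
        )
        if species == FOCAL:
            ann_b, pcs_b = classify(sp_dir / "annotation_b.tsv", f"{species}_partner")
            write_pair_table(
                pcs_b.bip + pcs_b.rh2h + pcs_b.h2t + pcs_b.t2t, sp_dir / "pairs_b.tsv"
            )
            for tag, a in (("a", ann), ("b", ann_b)):
                with open(sp_dir / f"random_pairs_{tag}.tsv", "w", newline="") as fh:
                    w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                    w.writerow(["gene_a", "gene_b"])
                    w.writerows(sample_random_pairs(a, n=5000, seed=SEED))

    summary = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "species_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nBidirectional arrangement is prevalent in every synthetic genome;")
    print("the percentage rises as genome size falls, as planted.")


if __name__ == "__main__":
    main()
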
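"""Remove tandem-duplicate pairs from the focal species pair: score every
adjacent and random gene pair by Smith-Waterman protein alignment with
Karlin-Altschul e-values and drop pairs below the 0.01 cutoff."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, FOCAL, RESULTS

import pandas as pd

from bipscan.dupfilter import read_fasta_proteins, remove_tandem_duplicates, write_removal_log
from bipscan.genome import read_annotation, sort_by_tss
from bipscan.pairs import enumerate_adjacent_pairs, identify_bip


def filter_species(tag: str):
    sp_dir = DATA / FOCAL
    ann = read_annotation(sp_dir / f"annotation_{tag}.tsv", species=f"{FOCAL}_{tag}")
    pcs = identify_bip(enumerate_adjacent_pairs(sort_by_tss(ann)))
    rnd = pd.read_csv(sp_dir / f"random_pairs_{tag}.tsv", sep="\t")
    pcs.random_pairs = list(rnd.itertuples(index=False, name=None))
    proteins = read_fasta_proteins(sp_dir / f"proteins_{tag}.fasta")
    filtered, removed = remove_tandem_duplicates(pcs, sequences=proteins)
    write_removal_log(removed, RESULTS / f"duplicate_removals_{tag}.tsv")
    kept = pd.DataFrame(
        [
            (p.gene_a.id, p.gene_b.id, cls, p.tss_distance)
            for cls, members in filtered.classes().items()
            for p in members
        ],
        columns=["gene_a", "gene_b", "pair_class", "tss_distance"],
    )
    kept.to_csv(RESULTS / f"filtered_pairs_{tag}.tsv", sep="\t", index=False)
    pd.DataFrame(filtered.random_pairs, columns=["gene_a", "gene_b"]).to_csv(
        RESULTS / f"filtered_random_{tag}.tsv", sep="\t", index=False
    )
    return pcs, filtered, removed


def main() -> None:
    for tag in ("a", "b"):
        pcs, filtered, removed = filter_species(tag)
        n_in = sum(len(v) for v in pcs.classes().values()) + len(pcs.random_pairs)
        n_out = sum(len(v) for v in filtered.classes().values()) + len(filtered.random_pairs)
        n_dup_like = sum(r.e_value < 1e-30 for r in removed)
        print(
            f"species {tag}: {n_in} pairs in, {n_out} kept, {len(removed)} removed "
            f"at E<0.01 ({n_dup_like} with E<1e-30, i.e. true duplicate-grade similarity)"
        )


if __name__ == "__main__":
    main()
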
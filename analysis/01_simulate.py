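"""Generate the synthetic study inputs: eight species' gene annotations
with c-value-linked intergenic structure, plus the full input bundle
(proteins, expression, ontology, pathways, orthologs) for the focal
species pair.  Everything downstream reads these files."""

import csv
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, FOCAL, SEED, species_meta_path

from bipscan.simulate import generate_dataset, octet_configs, write_dataset


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    configs = octet_configs(SEED)
    with open(species_meta_path(), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["species", "c_value", "planted_bip_fraction"])
        for cfg in configs:
            writer.writerow([cfg.species, cfg.c_value, cfg.bip_fraction])

    for cfg in configs:
        full = cfg.species == FOCAL
        ds = generate_dataset(
            cfg,
            with_proteins=full,
            with_expression=full,
            with_ontology=full,
            with_pathways=True,
            with_partner=full,
        )
        write_dataset(ds, DATA / cfg.species)
        print(f"{cfg.species}: {len(ds.annotation)} genes, "
              f"{len(ds.truth.planted_bip)} planted divergent pairs")

    print(f"wrote inputs for {len(configs)} species under {DATA}")


if __name__ == "__main__":
    main()
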
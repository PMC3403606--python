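"""Shared constants and paths for the numbered analysis drivers.

Each driver regenerates or reads deterministic inputs under
``results/data`` and writes its stage's tables under ``results``; run
them in order (01 first).
"""

from pathlib import Path

SEED = 2024

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

FOCAL = "synth_hs"   # focal species (full expression/GO/ortholog bundle)
PARTNER = "synth_hs_partner"


def species_meta_path() -> Path:
    return DATA / "species_meta.tsv"
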
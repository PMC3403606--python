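import numpy as np
import pytest

from bipscan.genome import Gene, GenomeAnnotation
from bipscan.simulate import SynthesisConfig, generate_annotation


def make_gene(gid, chrom="chr1", strand="+", start=100, end=500, biotype="protein_coding"):
    return Gene(id=gid, chromosome=chrom, strand=strand, start=start, end=end, biotype=biotype)


@pytest.fixture
def random_annotation():
    """1000 genes with random layout on 4 chromosomes (no planted pairs)."""
    rng = np.random.default_rng(42)
    genes = []
    for i in range(1000):
        start = int(rng.integers(1, 10_000_000))
        genes.append(
            Gene(
                id=f"G{i:04d}",
                chromosome=f"chr{1 + i % 4}",
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=start + int(rng.integers(100, 10_000)),
            )
        )
    return GenomeAnnotation(species="rand", genes=genes)


@pytest.fixture(scope="session")
def planted_dataset():
    """Medium synthetic genome with 30% of genes in planted divergent pairs."""
    cfg = SynthesisConfig(seed=7, genes_per_chromosome=400, bip_fraction=0.3)
    annotation, truth = generate_annotation(cfg)
    return cfg, annotation, truth
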
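"""Gene annotations, TSS derivation, and per-chromosome TSS ordering.

Genes are strand-aware genomic intervals in 1-based inclusive coordinates
(the GFF3 dialect).  The transcription start site (TSS) of a gene is its
5' end: ``start`` on the plus strand, ``end`` on the minus strand.  Because
some annotation exports report a strand-agnostic "gene start", a
``tss_mode`` switch reproduces either reading.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "DEFAULT_CHROM_EXCLUSIONS",
    "tss",
    "read_annotation",
    "write_annotation_tsv",
    "sort_by_tss",
]

#: Chromosome names dropped at load time: mitochondrial genomes and
#: unmapped/unplaced fragments are excluded from the analysis.
DEFAULT_CHROM_EXCLUSIONS: tuple[str, ...] = (
    "MT",
    "chrM",
    "chrMT",
    "Mito",
    "mitochondrion",
)

TssMode = Literal["five_prime", "lower_coordinate"]

ANNOTATION_TSV_HEADER = ["gene_id", "chromosome", "strand", "start", "end", "biotype"]


@dataclass(frozen=True, slots=True)
class Gene:
    """A gene locus: strand-aware interval from which the TSS is derived."""

    id: str
    chromosome: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.id!r}: start ({self.start}) > end ({self.end})")

    @property
    def tss(self) -> int:
        """5' end: ``start`` on '+', ``end`` on '-'."""
        return self.start if self.strand == "+" else self.end


def tss(gene: Gene, mode: TssMode = "five_prime") -> int:
    """Transcription start site of ``gene``.

    ``five_prime`` (default) returns the strand-aware 5' end; the
    ``lower_coordinate`` mode returns ``start`` regardless of strand,
    matching annotation exports whose "gene start" column is
    strand-agnostic.
    """
    if mode == "five_prime":
        return gene.tss
    if mode == "lower_coordinate":
        return gene.start
    raise ValueError(f"unknown tss_mode {mode!r}")


@dataclass
class GenomeAnnotation:
    """A species' gene set plus its haploid genome size (c-value, pg)."""

    species: str
    genes: list[Gene]
    c_value: float | None = None
    _by_id: dict[str, Gene] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.c_value is not None and self.c_value <= 0:
            raise ValueError("c_value must be positive (picograms)")
        self._by_id = {}
        for g in self.genes:
            if g.id in self._by_id:
                raise ValueError(f"duplicate gene id {g.id!r}")
            self._by_id[g.id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chromosomes(self) -> list[str]:
        return sorted({g.chromosome for g in self.genes})


class AnnotationParseError(ValueError):
    """A record in an annotation file could not be parsed."""


def _filter_genes(
    genes: Iterable[Gene],
    biotype_filter: tuple[str, ...] | None,
    chrom_exclusions: tuple[str, ...],
) -> list[Gene]:
    excl = set(chrom_exclusions)
    out = []
    for g in genes:
        if g.chromosome in excl:
            continue
        if biotype_filter is not None and g.biotype not in biotype_filter:
            continue
        out.append(g)
    return out


def _read_gff3_genes(path: Path) -> list[Gene]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        biotype = (
            feat.attributes.get("biotype")
            or feat.attributes.get("gene_biotype")
            or ["protein_coding"]
        )[0]
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("gene_id") or [feat.id])[0]
        genes.append(
            Gene(
                id=gene_id,
                chromosome=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                biotype=biotype,
            )
        )
    return genes


def _read_tsv_genes(path: Path) -> list[Gene]:
    genes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ANNOTATION_TSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise AnnotationParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                genes.append(
                    Gene(
                        id=row["gene_id"],
                        chromosome=row["chromosome"],
                        strand=row["strand"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        biotype=row["biotype"] or "protein_coding",
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_annotation(
    path: str | Path,
    fmt: Literal["gff3", "tsv"] = "tsv",
    species: str = "unknown",
    biotype_filter: tuple[str, ...] | None = ("protein_coding",),
    chrom_exclusions: tuple[str, ...] = DEFAULT_CHROM_EXCLUSIONS,
    c_value: float | None = None,
) -> GenomeAnnotation:
    """Load a gene annotation from GFF3 or a tab-separated gene table.

    Only genes whose biotype is in ``biotype_filter`` (``None`` keeps all)
    and whose chromosome is not excluded are retained.  Mitochondrial and
    unplaced-fragment chromosome names are excluded by default.
    """
    path = Path(path)
    if fmt == "gff3":
        genes = _read_gff3_genes(path)
    elif fmt == "tsv":
        genes = _read_tsv_genes(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes = _filter_genes(genes, biotype_filter, chrom_exclusions)
    return GenomeAnnotation(species=species, genes=genes, c_value=c_value)


def write_annotation_tsv(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_TSV_HEADER)
        for g in annotation.genes:
            writer.writerow([g.id, g.chromosome, g.strand, g.start, g.end, g.biotype])


def sort_by_tss(
    annotation: GenomeAnnotation, tss_mode: TssMode = "five_prime"
) -> dict[str, list[Gene]]:
    """Order genes within each chromosome by non-decreasing TSS.

    Ties are broken deterministically by (start, id).
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (tss(g, tss_mode), g.start, g.id))
    return dict(sorted(by_chrom.items()))
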
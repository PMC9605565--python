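"""Annotated genome container and FASTA/GFF3 round-trip.

The :class:`AnnotatedGenome` is the coordinate frame for every other
module: chromosome sequences plus single-exon gene/CDS records carrying
an essentiality flag (the annotation style of compact fungal genomes,
where nearly all genes are intron-free).  All serialized coordinates are
1-based inclusive.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class GenomeError(ValueError):
    """Inconsistent genome or annotation."""


@dataclass(frozen=True)
class GeneRecord:
    """A single-exon protein-coding gene; the interval is the CDS."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    essential: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise GenomeError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Named chromosome sequences plus gene records.

    Invariants (checked by :meth:`validate`): every gene lies within its
    chromosome, CDS lengths are positive multiples of 3, gene ids are
    unique.
    """

    chromosomes: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)

    def validate(self) -> "AnnotatedGenome":
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise GenomeError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self.chromosomes:
                raise GenomeError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise GenomeError(f"{g.gene_id}: extends past end of {g.chrom}")
            if g.length % 3 != 0:
                raise GenomeError(f"{g.gene_id}: CDS length {g.length} not a multiple of 3")
        return self

    # -- coordinate access ------------------------------------------------

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        seq = self.chromosomes[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise GenomeError(f"bad interval {chrom}:{start}-{end}")
        return seq[start - 1 : end]

    def chrom_length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.chrom == chrom]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def cds_sequence(self, gene: GeneRecord) -> str:
        """Coding sequence of a gene, 5'->3' on the gene strand."""
        seq = self.fetch(gene.chrom, gene.start, gene.end)
        return seq if gene.strand == "+" else str(Seq(seq).reverse_complement())

    def copy(self) -> "AnnotatedGenome":
        return AnnotatedGenome(dict(self.chromosomes), [replace(g) for g in self.genes])

    # -- I/O --------------------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)

    def write_gff3(self, path: str | Path) -> None:
        """GFF3 with gene + CDS features; essentiality as ``essential=`` attribute."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.chromosomes.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                ess = "true" if g.essential else "false"
                attrs = f"ID={g.gene_id};essential={ess}"
                fh.write(
                    f"{g.chrom}\tedit_aftermath\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{g.chrom}\tedit_aftermath\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                    f"ID=cds-{g.gene_id};Parent={g.gene_id}\n"
                )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path | None = None) -> "AnnotatedGenome":
        chromosomes = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        genes: list[GeneRecord] = []
        if gff3 is not None:
            db = gffutils.create_db(
                str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
            )
            for feat in db.features_of_type("gene"):
                ess = feat.attributes.get("essential", ["false"])[0].lower() == "true"
                genes.append(
                    GeneRecord(
                        gene_id=feat.id,
                        chrom=feat.seqid,
                        start=feat.start,
                        end=feat.end,
                        strand=feat.strand,
                        essential=ess,
                    )
                )
        return cls(chromosomes, genes).validate()
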
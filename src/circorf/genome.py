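"""Genome container and FASTA/GFF3 round-trip.

A :class:`GenomeBundle` holds contig sequences plus a flat gene model (one
representative transcript per gene, given by its ordered exons).  All
coordinates are 0-based half-open internally; GFF3 output follows the GFF3
standard (1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .errors import InputError

__all__ = ["Gene", "GenomeBundle", "revcomp"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return reverse_complement(seq)


@dataclass(frozen=True)
class Gene:
    """One gene with its representative transcript.

    ``exons`` are 0-based half-open genomic intervals, sorted and
    non-overlapping.  ``cds_start`` is the genomic position of the first base
    of the annotated start codon in transcript orientation (for a minus-strand
    gene this is the *highest* coordinate of the ATG), or ``None`` when no CDS
    is annotated.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = self.start - 1
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise InputError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")
            if s < prev_end:
                raise InputError(f"gene {self.gene_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position (on an exon) to transcript coordinates."""
        off = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= pos < e:
                    return off + (pos - s)
                off += e - s
        else:
            for s, e in reversed(self.exons):
                if s <= pos < e:
                    return off + (e - 1 - pos)
                off += e - s
        raise InputError(f"gene {self.gene_id}: position {pos} not exonic")


@dataclass
class GenomeBundle:
    """Contig sequences + gene annotation; the coordinate ground truth."""

    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig not in self.contigs:
                raise InputError(f"gene {g.gene_id}: unknown contig {g.contig}")
            if g.end > len(self.contigs[g.contig]):
                raise InputError(f"gene {g.gene_id}: span exceeds contig length")

    def genes_on(self, contig: str) -> list[Gene]:
        return [g for g in self.genes if g.contig == contig]

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise InputError(f"unknown gene {gene_id}")

    def transcript_seq(self, gene: Gene) -> str:
        """Spliced representative transcript, 5'->3' on the coding strand."""
        contig = self.contigs[gene.contig]
        spliced = "".join(contig[s:e] for s, e in gene.exons)
        return spliced if gene.strand == "+" else revcomp(spliced)

    def cds_offset(self, gene: Gene) -> int | None:
        """Transcript-coordinate offset of the annotated start codon."""
        if gene.cds_start is None:
            return None
        return gene.genomic_to_transcript(gene.cds_start)

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        """Emit gene/mRNA/exon features (1-based inclusive per the standard)."""
        lines = ["##gff-version 3"]
        for name, seq in self.contigs.items():
            lines.append(f"##sequence-region {name} 1 {len(seq)}")
        for g in self.genes:
            attrs = f"ID={g.gene_id}"
            if g.cds_start is not None:
                attrs += f";cds_start={g.cds_start + 1}"
            lines.append(
                "\t".join(
                    [g.contig, "circorf", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                )
            )
            mrna = f"{g.gene_id}.t1"
            lines.append(
                "\t".join(
                    [g.contig, "circorf", "mRNA", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]
                )
            )
            for i, (s, e) in enumerate(g.exons, 1):
                lines.append(
                    "\t".join(
                        [g.contig, "circorf", "exon", str(s + 1), str(e),
                         ".", g.strand, ".", f"ID={mrna}.e{i};Parent={mrna}"]
                    )
                )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, fasta: str | Path, gff3: str | Path) -> "GenomeBundle":
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        db = gffutils.create_db(
            str(gff3), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes: list[Gene] = []
        for gf in db.features_of_type("gene", order_by="start"):
            exons = []
            for mrna in db.children(gf, featuretype="mRNA"):
                for ex in db.children(mrna, featuretype="exon", order_by="start"):
                    exons.append((ex.start - 1, ex.end))
            cds_start = None
            if "cds_start" in gf.attributes:
                cds_start = int(gf.attributes["cds_start"][0]) - 1
            genes.append(
                Gene(
                    gene_id=gf.id,
                    contig=gf.seqid,
                    strand=gf.strand,
                    start=gf.start - 1,
                    end=gf.end,
                    exons=tuple(sorted(exons)),
                    cds_start=cds_start,
                )
            )
        return cls(contigs=contigs, genes=genes)
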
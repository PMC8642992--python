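"""Back-splice junction classification and circle reconstruction.

Every back-splice junction (BSJ) call is placed into exactly one of five
genomic categories — exonic, intronic, intergenic, sense-overlapping,
antisense — and, for downstream work, its full-length circular sequence is
reconstructed from the genome.

Sequence registration convention: position 0 of a circle is the first base
downstream of the back-splice junction (the splice-acceptor side), so the
junction sits between the last and the first base of the string.  All
junction-spanning arithmetic downstream relies on this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InputError
from .genome import Gene, GenomeBundle, revcomp

__all__ = [
    "CATEGORIES",
    "BSJRecord",
    "BackspliceEvent",
    "classify_circ",
    "reconstruct_sequence",
    "circ_length",
    "summarize_catalog",
    "category_percentages",
    "round_half_up",
    "read_bsj_bed",
    "write_bsj_bed",
    "write_catalog",
]

CATEGORIES = ("exonic", "intronic", "intergenic", "sense_overlapping", "antisense")


@dataclass(frozen=True)
class BSJRecord:
    """A raw BSJ call: 0-based half-open genomic interval plus strand."""

    circ_id: str
    contig: str
    start: int
    end: int
    strand: str

    def validate(self) -> None:
        if self.start >= self.end:
            raise InputError(
                f"BSJ {self.circ_id}: malformed interval start={self.start} >= end={self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"BSJ {self.circ_id}: strand must be + or -")


@dataclass(frozen=True)
class BackspliceEvent:
    """A classified, sequence-resolved circRNA candidate.

    ``sequence`` is the circular nucleotide string 5'->3' on the transcribed
    strand, beginning at the splice-acceptor end; ``exon_blocks`` are the
    genomic intervals (0-based half-open, genomic order) composing the circle.
    """

    circ_id: str
    contig: str
    start: int
    end: int
    strand: str
    category: str
    exon_blocks: tuple[tuple[int, int], ...]
    sequence: str

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    def junction_kmer(self, anchor: int = 10) -> str:
        """The 2*anchor-mer straddling the BSJ: last anchor + first anchor nt."""
        doubled = self.sequence * (2 + (2 * anchor) // max(len(self.sequence), 1))
        L = len(self.sequence)
        return doubled[L - anchor : L + anchor]

    def offset_of(self, genomic_pos: int) -> int:
        """Circle offset (registration above) of an exonic genomic position."""
        off = 0
        blocks = self.exon_blocks if self.strand == "+" else tuple(reversed(self.exon_blocks))
        for s, e in blocks:
            if s <= genomic_pos < e:
                return off + (genomic_pos - s if self.strand == "+" else e - 1 - genomic_pos)
            off += e - s
        raise InputError(f"{self.circ_id}: position {genomic_pos} not inside circle blocks")


def _overlapping_genes(rec: BSJRecord, genome: GenomeBundle) -> list[Gene]:
    return [g for g in genome.genes_on(rec.contig) if g.overlaps(rec.start, rec.end)]


def _exonic_gene(rec: BSJRecord, genes: list[Gene]) -> Gene | None:
    for g in genes:
        if g.strand != rec.strand:
            continue
        starts = {s for s, _ in g.exons}
        ends = {e for _, e in g.exons}
        if rec.start in starts and rec.end in ends:
            return g
    return None


def classify_circ(rec: BSJRecord, genome: GenomeBundle) -> str:
    """Assign exactly one category, by precedence.

    1. *exonic* — both BSJ ends coincide with exon boundaries of a same-strand
       gene; 2. *intronic* — the span lies entirely within one intron of a
       same-strand gene; 3. *sense_overlapping* — overlaps a same-strand gene
       but neither rule applies; 4. *antisense* — overlaps only opposite-strand
       genes; 5. *intergenic* otherwise.  Precedence makes the categories
       mutually exclusive and the most information-rich call win.
    """
    rec.validate()
    if rec.contig not in genome.contigs:
        raise InputError(f"BSJ {rec.circ_id}: unknown contig {rec.contig}")
    genes = _overlapping_genes(rec, genome)
    if _exonic_gene(rec, genes) is not None:
        return "exonic"
    same = [g for g in genes if g.strand == rec.strand]
    for g in same:
        for istart, iend in g.introns:
            if istart <= rec.start and rec.end <= iend:
                return "intronic"
    if same:
        return "sense_overlapping"
    if genes:
        return "antisense"
    return "intergenic"


def reconstruct_sequence(
    rec: BSJRecord, genome: GenomeBundle, category: str | None = None
) -> BackspliceEvent:
    """Build the full-length circular sequence for a BSJ call.

    Exonic circles are the concatenation of the annotated exon blocks within
    the BSJ span (introns removed); all other categories take the genomic
    span.  Minus-strand circles are reverse-complemented so the sequence reads
    5'->3' starting at the acceptor, which keeps the junction between the last
    and first base.
    """
    if category is None:
        category = classify_circ(rec, genome)
    rec.validate()
    contig_seq = genome.contigs[rec.contig]
    if rec.end > len(contig_seq):
        raise InputError(f"BSJ {rec.circ_id}: blocks outside contig {rec.contig}")
    if category == "exonic":
        gene = _exonic_gene(rec, _overlapping_genes(rec, genome))
        if gene is None:
            raise InputError(f"BSJ {rec.circ_id}: classified exonic but no boundary-matched gene")
        blocks = tuple(
            (s, e) for s, e in gene.exons if s >= rec.start and e <= rec.end
        )
    else:
        blocks = ((rec.start, rec.end),)
    spliced = "".join(contig_seq[s:e] for s, e in blocks)
    if rec.strand == "-":
        spliced = revcomp(spliced)
    return BackspliceEvent(
        circ_id=rec.circ_id,
        contig=rec.contig,
        start=rec.start,
        end=rec.end,
        strand=rec.strand,
        category=category,
        exon_blocks=blocks,
        sequence=spliced,
    )


def circ_length(rec: BSJRecord | BackspliceEvent) -> int:
    """Circle length in nt: end - start for a single block, else sum of blocks."""
    if isinstance(rec, BackspliceEvent):
        return rec.length
    rec.validate()
    return rec.end - rec.start


def round_half_up(x: float) -> int:
    """Round with ties away from zero toward +inf (0.5 -> 1), for percentages."""
    return int(math.floor(x + 0.5))


def category_percentages(counts: dict[str, int]) -> dict[str, int]:
    """Per-category integer percentages (half-up rounding) of a count table."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0 for k in counts}
    return {k: round_half_up(100.0 * v / total) for k, v in counts.items()}


def summarize_catalog(events: list[BackspliceEvent]) -> dict:
    """Category counts + rounded percentages and a length histogram.

    The histogram uses 500-nt bins up to 3000 nt plus an overflow bin, and the
    summary reports the fraction of circles shorter than 1500 nt.  An empty
    catalog yields an explicit empty-summary marker rather than an error.
    """
    if not events:
        return {"n": 0, "empty": True, "counts": {}, "percent": {}, "length_hist": {}}
    counts = {c: 0 for c in CATEGORIES}
    for ev in events:
        counts[ev.category] += 1
    lengths = [ev.length for ev in events]
    edges = [0, 500, 1000, 1500, 2000, 2500, 3000]
    hist: dict[str, int] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        hist[f"[{lo},{hi})"] = sum(lo <= L < hi for L in lengths)
    hist[">=3000"] = sum(L >= 3000 for L in lengths)
    return {
        "n": len(events),
        "empty": False,
        "counts": counts,
        "percent": category_percentages(counts),
        "length_hist": hist,
        "frac_lt_1500": sum(L < 1500 for L in lengths) / len(events),
    }


# --------------------------------------------------------------------- I/O


def read_bsj_bed(path: str | Path, one_based: bool = False) -> list[BSJRecord]:
    """Read BSJ calls from BED6 (0-based half-open; ``one_based`` converts
    GFF-style 1-based inclusive starts)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "name": str, "strand": str},
    )
    recs = []
    for row in df.itertuples(index=False):
        start = int(row.start) - 1 if one_based else int(row.start)
        recs.append(BSJRecord(row.name, row.contig, start, int(row.end), row.strand))
    return recs


def write_bsj_bed(records: list[BSJRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.circ_id}\t0\t{r.strand}\n")


def write_catalog(events: list[BackspliceEvent], tsv: str | Path, fasta: str | Path) -> None:
    """Annotated catalog TSV + circular sequences FASTA (header carries
    circ_id, coordinates and category)."""
    rows = [
        {
            "circ_id": ev.circ_id, "contig": ev.contig, "start": ev.start,
            "end": ev.end, "strand": ev.strand, "category": ev.category,
            "length": ev.length,
            "blocks": ",".join(f"{s}-{e}" for s, e in ev.exon_blocks),
        }
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
    with open(fasta, "w") as fh:
        for ev in events:
            fh.write(
                f">{ev.circ_id} {ev.contig}:{ev.start}-{ev.end}({ev.strand}) {ev.category}\n"
            )
            for i in range(0, len(ev.sequence), 70):
                fh.write(ev.sequence[i : i + 70] + "\n")
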
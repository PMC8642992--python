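"""Synthetic study generator: toy genome, planted circRNAs, counts, reads.

The generator emulates the study design the screen assumes: a multi-gene toy
genome with exon structures on both strands; back-splice events in five
genomic categories at configurable proportions; a configurable number of
planted *coding* circles structurally analogous to a validated coding
circRNA — a single-exon circle whose ORF starts at the parental gene's
annotated start codon, crosses the back-splice junction, and terminates with
exactly two novel C-terminal residues ("TD") shortly after the crossing, with
a polypyrimidine IRES-like tract upstream of the start; and paired
tumor/normal negative-binomial counts with planted fold changes and a
recurrence pattern.

Determinism: one global seed; per-stage substreams are derived by fixed
offsets so stages can be regenerated independently.  All outputs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import annotate as ann
from . import coding
from .errors import CircOrfError, ConfigurationError
from .genome import Gene, GenomeBundle, revcomp
from .quant import CountMatrix

__all__ = [
    "SimConfig",
    "TruthRecord",
    "allocate_categories",
    "generate_genome",
    "plant_circrnas",
    "simulate_counts",
    "simulate_junction_reads",
    "write_fastq",
    "write_truth",
    "read_truth",
]

DEFAULT_MIX = {
    "exonic": 0.79,
    "intronic": 0.01,
    "intergenic": 0.04,
    "sense_overlapping": 0.15,
    "antisense": 0.01,
}

# fixed layout of a planted coding circle (offsets on the circle):
# [0,9)   "ACAGATTAA" — the wrapped tail: Thr, Asp, stop after the junction
# tract   polypyrimidine IRES-like run at [orf_start-55, orf_start-10)
# [s-3,s) "TAA" — in-frame stop guarding against upstream starts
# [s,s+3) "ATG", then a stop-free, internal-ATG-free codon body to position L
_WRAP_TAIL = "ACAGATTAA"
_NOVEL_SUFFIX_AA = "TD"
_TRACT_SPAN = (55, 10)  # relative to orf_start: [s-55, s-10)


@dataclass
class SimConfig:
    """All knobs of the synthetic study; the defaults ARE the study design."""

    seed: int = 1
    n_contigs: int = 2
    contig_length: int = 80_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (1, 4)
    n_circs: int = 100
    n_coding: int = 6
    n_up_noncoding: int = 4
    category_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    n_pairs: int = 5
    planted_fc: float = 6.0
    noncoding_up_pairs: int = 3
    nb_dispersion: float = 0.05
    depth: float = 100.0
    read_length: int = 50
    anchor: int = 10
    linear_ratio_range: tuple[float, float] = (0.01, 0.06)
    analog_exon_length: int = 959

    def validate(self) -> None:
        if set(self.category_mix) != set(DEFAULT_MIX):
            raise ConfigurationError(
                f"category_mix must have exactly the categories {sorted(DEFAULT_MIX)}"
            )
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("category_mix fractions must sum to 1 (± 1e-9)")
        if self.planted_fc <= 1:
            raise ConfigurationError("planted_fc must be > 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.n_pairs < 2:
            raise ConfigurationError("n_pairs must be >= 2")
        if self.noncoding_up_pairs > self.n_pairs:
            raise ConfigurationError("noncoding_up_pairs cannot exceed n_pairs")
        lo, hi = self.exons_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("exons_per_gene range invalid")
        if self.read_length < 2 * self.anchor:
            raise ConfigurationError("read_length must be >= 2 * anchor")
        if self.n_coding > self.n_genes:
            raise ConfigurationError("n_coding cannot exceed n_genes")


@dataclass
class TruthRecord:
    """Ground truth for one planted circRNA."""

    circ_id: str
    contig: str
    start: int
    end: int
    strand: str
    true_category: str
    true_coding: bool
    true_orf_protein: str | None
    true_orf_start: int | None  # 0-based offset on the circle
    true_fc_per_pair: tuple[float, ...]
    ires_interval: tuple[int, int] | None  # 1-based inclusive on the circle
    sequence: str
    host_gene: str | None
    linear_seq: str | None

    def __post_init__(self) -> None:
        if self.true_coding and not self.true_orf_protein:
            raise CircOrfError(f"{self.circ_id}: coding truth requires an ORF protein")
        if self.ires_interval is not None:
            s, e = self.ires_interval
            if not (1 <= s <= e <= len(self.sequence)):
                raise CircOrfError(f"{self.circ_id}: IRES interval outside circle")

    def to_bsj(self) -> ann.BSJRecord:
        return ann.BSJRecord(self.circ_id, self.contig, self.start, self.end, self.strand)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def allocate_categories(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of n circles to categories (exact totals)."""
    cats = list(mix)
    floors = {c: int(np.floor(mix[c] * n)) for c in cats}
    rem = n - sum(floors.values())
    frac = sorted(cats, key=lambda c: (-(mix[c] * n - floors[c]), cats.index(c)))
    for c in frac[:rem]:
        floors[c] += 1
    return floors


# -------------------------------------------------------------- genome


_BASES = np.array(list("ACGT"))
_PYR = np.array(list("CT"))
# codon alphabet for the ORF body: no stop codons, no internal ATG
_BODY_CODONS = np.array(
    [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
    ]
)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _coding_exon(
    rng: np.random.Generator, length: int, analog: bool = False
) -> tuple[str, int, str, tuple[int, int]]:
    """Build a planted coding exon; returns (sequence, orf_start, protein, ires 1-based).

    The construction is validated by re-running the ORF finder and IRES
    scanner on the circle; the ORF start is nudged in codon steps until the
    IRES window grid can see the planted tract.  The analog host uses ORF
    start 80, which on a 959-nt circle yields a 295-aa junction-spanning
    protein — the geometry of the validated coding circle.
    """
    L = length
    base_s = 80 if analog else 64  # tract must clear the wrap tail (s - 55 >= 9)
    base_s += (L - base_s) % 3  # (L - s) divisible by 3: junction falls between codons
    last_err = "unknown"
    for bump in range(0, 30, 3):
        s = base_s + bump
        if s + 3 >= L or s > 0.4 * L:
            break
        seq = list(_random_seq(rng, L))
        seq[0:9] = list(_WRAP_TAIL)
        t_lo, t_hi = s - _TRACT_SPAN[0], s - _TRACT_SPAN[1]
        seq[t_lo:t_hi] = list("".join(_PYR[rng.integers(0, 2, t_hi - t_lo)]))
        seq[s - 3 : s] = list("TAA")
        seq[s : s + 3] = list("ATG")
        n_body = (L - (s + 3)) // 3
        seq[s + 3 : L] = list("".join(_BODY_CODONS[rng.integers(0, len(_BODY_CODONS), n_body)]))
        circle = "".join(seq)
        orf_nt = circle[s:] + circle[:6]
        protein = str(Seq(orf_nt).translate())
        if "*" in protein:
            last_err = "internal stop"
            continue
        found = [o for o in coding.find_circular_orfs(circle) if o.protein == protein]
        if not found or not found[0].spans_junction:
            last_err = "ORF not recovered"
            continue
        hits = coding.scan_ires(circle)
        covered = any(h.start <= t_lo + 1 and h.end >= t_lo + 10 for h in hits) or any(
            h.start - 1 < t_hi and h.end > t_lo for h in hits
        )
        if not covered:
            last_err = "IRES tract not detectable on the window grid"
            continue
        return circle, s, protein, (t_lo + 1, t_hi)
    raise CircOrfError(
        f"could not construct a coding exon of length {length} ({last_err}); "
        "try a different seed or exon length"
    )


def generate_genome(config: SimConfig) -> GenomeBundle:
    """Deterministic toy genome: genes on both strands, the first
    ``n_coding`` genes are single-exon coding hosts (the first of them the
    959-nt analog of the validated coding circle)."""
    config.validate()
    rng = _rng(config, 1)
    contig_names = [f"chr{i + 1}" for i in range(config.n_contigs)]
    contigs = {name: list(_random_seq(rng, config.contig_length)) for name in contig_names}
    cursors = {name: 0 for name in contig_names}
    genes: list[Gene] = []
    lo, hi = config.exons_per_gene
    for gi in range(config.n_genes):
        is_host = gi < config.n_coding
        strand = "+" if gi % 2 == 0 else "-"
        if is_host:
            exon_len = (
                config.analog_exon_length
                if gi == 0
                else int(rng.integers(450, 751))
            )
            exon_lens = [exon_len]
            intron_lens = []
        else:
            n_ex = int(rng.integers(lo, hi + 1))
            exon_lens = [int(rng.integers(120, 481)) for _ in range(n_ex)]
            intron_lens = [int(rng.integers(100, 301)) for _ in range(n_ex - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        gap = int(rng.integers(200, 501))
        placed = None
        for name in contig_names:
            start = cursors[name] + gap
            if start + span <= config.contig_length:
                placed = (name, start)
                cursors[name] = start + span
                break
        if placed is None:
            raise ConfigurationError(
                f"contig shorter than required gene span for gene {gi}: "
                "increase contig_length or reduce n_genes"
            )
        name, gstart = placed
        exons = []
        pos = gstart
        for i, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen))
            pos += elen
            if i < len(intron_lens):
                pos += intron_lens[i]
        cds_start = None
        if is_host:
            circle, s, _protein, _ires = _coding_exon(rng, exon_lens[0], analog=(gi == 0))
            es, ee = exons[0]
            segment = circle if strand == "+" else revcomp(circle)
            contigs[name][es:ee] = list(segment)
            cds_start = es + s if strand == "+" else ee - 1 - s
        genes.append(
            Gene(
                gene_id=f"gene_{gi:03d}",
                contig=name,
                strand=strand,
                start=gstart,
                end=pos,
                exons=tuple(exons),
                cds_start=cds_start,
            )
        )
    return GenomeBundle(contigs={k: "".join(v) for k, v in contigs.items()}, genes=genes)


# ------------------------------------------------------------ planting


def _exon_run_pool(genes: list[Gene]) -> list[tuple[Gene, int, int]]:
    pool = []
    for g in genes:
        for i in range(len(g.exons)):
            for j in range(i, len(g.exons)):
                pool.append((g, i, j))
    return pool


def plant_circrnas(
    genome: GenomeBundle, config: SimConfig
) -> tuple[list[TruthRecord], list[ann.BSJRecord]]:
    """Plant BSJ events in the configured category proportions.

    The realized proportions equal the largest-remainder allocation of
    ``category_mix`` x ``n_circs`` (within ±2 by construction, exact here).
    Coding plants occupy one host gene each and count toward the exonic
    category.  Every planted attribute is re-derived through the annotation
    stage, so truth and catalog cannot drift apart.
    """
    config.validate()
    rng = _rng(config, 2)
    hosts = [g for g in genome.genes if g.cds_start is not None and len(g.exons) == 1]
    if len(hosts) < config.n_coding:
        raise CircOrfError(
            "no eligible host exon for a coding plant: the genome provides "
            f"{len(hosts)} single-exon CDS hosts but n_coding={config.n_coding}; "
            "regenerate the genome with matching n_coding"
        )
    counts = allocate_categories(config.category_mix, config.n_circs)
    if counts["exonic"] < config.n_coding:
        raise ConfigurationError("exonic allocation smaller than n_coding")
    non_host = [g for g in genome.genes if g.cds_start is None]
    used: set[tuple] = set()
    planned: list[tuple[str, ann.BSJRecord, Gene | None]] = []  # (category, rec, host)

    def reserve(contig, start, end, strand) -> bool:
        key = (contig, start, end, strand)
        if key in used:
            return False
        used.add(key)
        return True

    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"circ_{idx:04d}"

    coding_ids = []
    for g in hosts[: config.n_coding]:
        es, ee = g.exons[0]
        cid = next_id()
        reserve(g.contig, es, ee, g.strand)
        planned.append(("exonic", ann.BSJRecord(cid, g.contig, es, ee, g.strand), g))
        coding_ids.append(cid)

    pool = _exon_run_pool(non_host)
    order = rng.permutation(len(pool))
    taken = 0
    need = counts["exonic"] - config.n_coding
    for k in order:
        if taken == need:
            break
        g, i, j = pool[k]
        s, e = g.exons[i][0], g.exons[j][1]
        if reserve(g.contig, s, e, g.strand):
            planned.append(("exonic", ann.BSJRecord(next_id(), g.contig, s, e, g.strand), g))
            taken += 1
    if taken < need:
        raise CircOrfError(
            f"only {taken} of {need} exonic circles could be planted; "
            "increase n_genes or exons_per_gene"
        )

    intron_genes = [g for g in non_host if len(g.exons) > 1]
    for _ in range(counts["intronic"]):
        if not intron_genes:
            raise CircOrfError("no multi-exon gene available for an intronic plant")
        for _try in range(100):
            g = intron_genes[rng.integers(0, len(intron_genes))]
            istart, iend = g.introns[rng.integers(0, len(g.introns))]
            max_len = min(iend - istart - 4, 400)
            if max_len < 80:
                continue
            ell = int(rng.integers(80, max_len + 1))
            s = istart + int(rng.integers(1, iend - istart - ell))
            if reserve(g.contig, s, s + ell, g.strand):
                planned.append(
                    ("intronic", ann.BSJRecord(next_id(), g.contig, s, s + ell, g.strand), g)
                )
                break
        else:
            raise CircOrfError("failed to place an intronic circle")

    for _ in range(counts["sense_overlapping"]):
        for _try in range(100):
            g = non_host[rng.integers(0, len(non_host))]
            ex = g.exons[rng.integers(0, len(g.exons))]
            s = ex[0] + int(rng.integers(5, 21))
            max_len = min(g.end - s, 400)
            if max_len < 80:
                continue
            ell = int(rng.integers(80, max_len + 1))
            if reserve(g.contig, s, s + ell, g.strand):
                planned.append(
                    ("sense_overlapping",
                     ann.BSJRecord(next_id(), g.contig, s, s + ell, g.strand), g)
                )
                break
        else:
            raise CircOrfError("failed to place a sense-overlapping circle")

    for _ in range(counts["antisense"]):
        for _try in range(100):
            g = genome.genes[rng.integers(0, len(genome.genes))]
            flipped = "-" if g.strand == "+" else "+"
            s = g.start + int(rng.integers(2, 20))
            max_len = min(g.end - s - 2, 400)
            if max_len < 80:
                continue
            ell = int(rng.integers(80, max_len + 1))
            if reserve(g.contig, s, s + ell, flipped):
                planned.append(
                    ("antisense", ann.BSJRecord(next_id(), g.contig, s, s + ell, flipped), g)
                )
                break
        else:
            raise CircOrfError("failed to place an antisense circle")

    for _ in range(counts["intergenic"]):
        gaps = []
        for cname, seq in genome.contigs.items():
            spans = sorted((g.start, g.end) for g in genome.genes_on(cname))
            prev = 0
            for gs, ge in spans:
                if gs - prev >= 160:
                    gaps.append((cname, prev, gs))
                prev = ge
            if len(seq) - prev >= 160:
                gaps.append((cname, prev, len(seq)))
        for _try in range(100):
            cname, lo_, hi_ = gaps[rng.integers(0, len(gaps))]
            max_len = min(hi_ - lo_ - 40, 400)
            ell = int(rng.integers(80, max_len + 1))
            s = lo_ + 20 + int(rng.integers(0, hi_ - lo_ - 40 - ell + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            if reserve(cname, s, s + ell, strand):
                planned.append(
                    ("intergenic", ann.BSJRecord(next_id(), cname, s, s + ell, strand), None)
                )
                break
        else:
            raise CircOrfError("failed to place an intergenic circle")

    # which non-coding circles carry a planted fold change
    noncoding_recs = [i for i, (cat, rec, _g) in enumerate(planned) if rec.circ_id not in coding_ids]
    up_noncoding = set(
        planned[i][1].circ_id
        for i in rng.permutation(noncoding_recs)[: config.n_up_noncoding]
    )

    truths: list[TruthRecord] = []
    bsjs: list[ann.BSJRecord] = []
    for cat, rec, host in planned:
        realized = ann.classify_circ(rec, genome)
        if realized != cat:
            raise CircOrfError(
                f"{rec.circ_id}: planted {cat} but classifies {realized}; generation bug"
            )
        ev = ann.reconstruct_sequence(rec, genome, category=realized)
        is_coding = rec.circ_id in coding_ids
        protein = orf_start = ires = None
        if is_coding:
            orf_start = ev.offset_of(host.cds_start)
            orf_nt = (ev.sequence * 2)[orf_start:] [: (ev.length - orf_start) + 6]
            protein = str(Seq(orf_nt).translate())
            ires = (orf_start - _TRACT_SPAN[0] + 1, orf_start - _TRACT_SPAN[1])
            fc = tuple([config.planted_fc] * config.n_pairs)
        elif rec.circ_id in up_noncoding:
            up = set(rng.choice(config.n_pairs, config.noncoding_up_pairs, replace=False))
            fc = tuple(config.planted_fc if p in up else 1.0 for p in range(config.n_pairs))
        else:
            fc = tuple([1.0] * config.n_pairs)
        linear_seq = genome.transcript_seq(host) if host is not None else None
        truths.append(
            TruthRecord(
                circ_id=rec.circ_id, contig=rec.contig, start=rec.start, end=rec.end,
                strand=rec.strand, true_category=realized, true_coding=is_coding,
                true_orf_protein=protein, true_orf_start=orf_start,
                true_fc_per_pair=fc, ires_interval=ires, sequence=ev.sequence,
                host_gene=host.gene_id if host else None, linear_seq=linear_seq,
            )
        )
        bsjs.append(rec)
    return truths, bsjs


# -------------------------------------------------------------- counts


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    nz = mean > 0
    out[nz] = rng.negative_binomial(n, p[nz])
    return out


def sample_design(n_pairs: int) -> pd.DataFrame:
    rows = []
    for p in range(1, n_pairs + 1):
        rows.append({"sample": f"pair{p}_tumor", "condition": "tumor", "pair": p})
        rows.append({"sample": f"pair{p}_normal", "condition": "normal", "pair": p})
    return pd.DataFrame(rows)


def simulate_counts(
    truth: list[TruthRecord], config: SimConfig
) -> tuple[CountMatrix, CountMatrix]:
    """Paired tumor/normal NB counts for circles and their parental transcripts.

    Planted circles have a per-pair tumor/normal expectation ratio equal to
    their planted fold change.  Parental linear counts are scaled so that the
    per-sample length-normalized circ/linear rate ratio is drawn once per
    circle from ``linear_ratio_range`` (the parental transcript tracks the
    circle across conditions).  Circles without a parental gene have no
    linear counterpart.
    """
    config.validate()
    rng = _rng(config, 3)
    design = sample_design(config.n_pairs)
    ids = [t.circ_id for t in truth]
    circ_len = pd.Series({t.circ_id: len(t.sequence) for t in truth})
    base = config.depth * rng.lognormal(mean=0.0, sigma=0.4, size=len(truth))
    fc = np.array([t.true_fc_per_pair for t in truth])  # features x pairs
    cols, data = [], []
    for p in range(config.n_pairs):
        t_mean = base * fc[:, p]
        n_mean = base
        data.append(_nb(rng, t_mean, config.nb_dispersion))
        cols.append(f"pair{p + 1}_tumor")
        data.append(_nb(rng, n_mean, config.nb_dispersion))
        cols.append(f"pair{p + 1}_normal")
    circ_counts = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    circ_cm = CountMatrix(circ_counts, circ_len, design)

    with_parent = [t for t in truth if t.linear_seq is not None]
    lin_ids = [t.circ_id for t in with_parent]
    lin_len = pd.Series({t.circ_id: len(t.linear_seq) for t in with_parent})
    lo, hi = config.linear_ratio_range
    ratio = rng.uniform(lo, hi, size=len(with_parent))
    sel = [ids.index(t.circ_id) for t in with_parent]
    lin_data, lin_cols = [], []
    for p in range(config.n_pairs):
        for cond in ("tumor", "normal"):
            circ_mean = base[sel] * (fc[sel, p] if cond == "tumor" else 1.0)
            lin_mean = circ_mean * (lin_len.to_numpy() / circ_len.to_numpy()[sel]) / ratio
            lin_data.append(_nb(rng, lin_mean, config.nb_dispersion))
            lin_cols.append(f"pair{p + 1}_{cond}")
    lin_counts = pd.DataFrame(np.column_stack(lin_data), index=lin_ids, columns=lin_cols)
    lin_cm = CountMatrix(lin_counts, lin_len, design)
    return circ_cm, lin_cm


# --------------------------------------------------------------- reads


def simulate_junction_reads(
    truth: list[TruthRecord], config: SimConfig
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """One untreated and one RNase-R-treated read set (id, sequence).

    Every circular-origin read straddles the junction with at least
    ``anchor`` nt on each side; linear-origin reads come from the parental
    transcript body.  The treated set retains all circular reads and no
    linear reads — the in-silico counterpart of exonuclease digestion of
    linear RNA.
    """
    config.validate()
    rng = _rng(config, 4)
    rl, a = config.read_length, config.anchor
    min_L = min(len(t.sequence) for t in truth)
    if rl >= min_L:
        raise ConfigurationError(
            f"read_length {rl} >= minimum circle length {min_L}"
        )
    circ_reads: list[tuple[str, str]] = []
    linear_reads: list[tuple[str, str]] = []
    for t in truth:
        L = len(t.sequence)
        doubled = t.sequence * 2
        n_reads = rng.poisson(config.depth)
        for i in range(n_reads):
            start = int(rng.integers(L - rl + a, L - a + 1))
            circ_reads.append((f"circ|{t.circ_id}|{i}", doubled[start : start + rl]))
        if t.linear_seq is not None and len(t.linear_seq) >= rl:
            n_lin = rng.poisson(config.depth)
            for i in range(n_lin):
                start = int(rng.integers(0, len(t.linear_seq) - rl + 1))
                linear_reads.append(
                    (f"lin|{t.circ_id}|{i}", t.linear_seq[start : start + rl])
                )
    untreated = circ_reads + linear_reads
    treated = list(circ_reads)
    return untreated, treated


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ----------------------------------------------------------------- I/O


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truth:
        rows.append(
            {
                "circ_id": t.circ_id, "contig": t.contig, "start": t.start,
                "end": t.end, "strand": t.strand, "category": t.true_category,
                "coding": int(t.true_coding),
                "orf_protein": t.true_orf_protein or "NA",
                "orf_start": t.true_orf_start if t.true_orf_start is not None else "NA",
                "fc_per_pair": ",".join(f"{x:g}" for x in t.true_fc_per_pair),
                "ires_start": t.ires_interval[0] if t.ires_interval else "NA",
                "ires_end": t.ires_interval[1] if t.ires_interval else "NA",
                "host_gene": t.host_gene or "NA",
                "sequence": t.sequence,
                "linear_seq": t.linear_seq or "NA",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            TruthRecord(
                circ_id=r.circ_id, contig=r.contig, start=int(r.start), end=int(r.end),
                strand=r.strand, true_category=r.category, true_coding=bool(int(r.coding)),
                true_orf_protein=None if r.orf_protein == "NA" else r.orf_protein,
                true_orf_start=None if r.orf_start == "NA" else int(r.orf_start),
                true_fc_per_pair=tuple(float(x) for x in r.fc_per_pair.split(",")),
                ires_interval=None if r.ires_start == "NA" else (int(r.ires_start), int(r.ires_end)),
                sequence=r.sequence,
                host_gene=None if r.host_gene == "NA" else r.host_gene,
                linear_seq=None if r.linear_seq == "NA" else r.linear_seq,
            )
        )
    return out
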
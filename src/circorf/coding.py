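"""Coding-potential screen on circular sequences.

The core operations: translate a circular template from an arbitrary start,
enumerate all AUG-initiated open reading frames (requiring, for coding
candidates, that the codon walk crosses the back-splice junction), flag
rolling-circle frames with no in-frame stop, scan for IRES-like regions, and
rank candidates through the discovery funnel (expression -> length ->
junction-spanning ORF -> ORF position -> IRES).

Geometry: position 0 of a circle is the first base after the junction, so a
codon walk "spans the junction" iff it crosses the boundary between position
L-1 and 0.  ORF nucleotide length includes the stop codon; the protein string
excludes it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .annotate import BackspliceEvent
from .errors import InputError, PipelineOrderError

__all__ = [
    "CircORF",
    "IRESHit",
    "Candidate",
    "CodingParams",
    "TranslationResult",
    "translate_circular",
    "find_circular_orfs",
    "scan_ires",
    "rank_candidates",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    stop_pos: int | None  # circle offset of the stop codon's first base
    nt_length: int  # start codon through stop codon inclusive (wrapped)
    rolling: bool
    ambiguous: bool  # hit an untranslatable (N-containing) codon


def translate_circular(sequence: str, start: int, max_cycles: int = 3) -> TranslationResult:
    """Translate codons read modulo L from ``start`` until the first in-frame
    stop, or flag rolling-circle after ``max_cycles`` full turns.

    Standard nuclear genetic code.  Ambiguity codes are never translated: a
    codon containing a non-ACGT base aborts the walk with ``ambiguous`` set.
    """
    L = len(sequence)
    if L < 3:
        raise InputError(f"circular sequence of length {L} < 3 cannot be translated")
    if not (0 <= start < L):
        raise InputError(f"translation start {start} outside [0, {L})")
    if max_cycles < 1:
        raise InputError("max_cycles must be >= 1")
    seq = sequence.upper()
    max_codons = math.ceil(max_cycles * L / 3)
    aas: list[str] = []
    pos = start
    for _ in range(max_codons):
        codon = seq[pos % L] + seq[(pos + 1) % L] + seq[(pos + 2) % L]
        if codon in STOP_CODONS:
            return TranslationResult(
                protein="".join(aas),
                stop_pos=pos % L,
                nt_length=3 * (len(aas) + 1),
                rolling=False,
                ambiguous=False,
            )
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            return TranslationResult(
                protein="".join(aas), stop_pos=None, nt_length=3 * len(aas),
                rolling=False, ambiguous=True,
            )
        aas.append(aa)
        pos += 3
    return TranslationResult(
        protein="".join(aas), stop_pos=None, nt_length=3 * len(aas),
        rolling=True, ambiguous=False,
    )


@dataclass(frozen=True)
class CircORF:
    """An ORF on a circular sequence.

    ``cycles_crossed`` counts junction crossings of the codon walk;
    ``spans_junction`` iff that count is >= 1.  Rolling-circle ORFs carry the
    protein truncated at the max-cycles cap and are flagged, never silently
    emitted as complete.
    """

    circ_id: str
    start: int
    frame: int
    nt_length: int
    aa_length: int
    spans_junction: bool
    rolling_circle: bool
    cycles_crossed: int
    protein: str
    stop_pos: int | None = None


def _orf_from_walk(circ_id: str, L: int, start: int, tr: TranslationResult) -> CircORF:
    span = start + tr.nt_length
    cycles = (span - 1) // L if tr.nt_length > 0 else 0
    return CircORF(
        circ_id=circ_id,
        start=start,
        frame=start % 3,
        nt_length=tr.nt_length,
        aa_length=len(tr.protein),
        spans_junction=cycles >= 1,
        rolling_circle=tr.rolling,
        cycles_crossed=cycles,
        protein=tr.protein,
        stop_pos=tr.stop_pos,
    )


def _dedup_key(orf: CircORF, L: int) -> tuple:
    # "longest per stop" applies to stopped walks only; rolling walks have no
    # stop to share, and collapsing them would break rotation covariance
    if orf.stop_pos is not None:
        return ("stop", orf.stop_pos)
    return ("rolling", orf.start)


def find_circular_orfs(
    event: BackspliceEvent | str,
    circ_id: str = "",
    max_cycles: int = 3,
    start_codons: tuple[str, ...] = ("ATG",),
) -> list[CircORF]:
    """All AUG-initiated ORFs on a circle, deduplicated to the longest per stop.

    Every start-codon occurrence on the circle is a candidate start.  Nested
    starts sharing a stop collapse to the longest (ties to the smaller start
    offset); rolling-circle walks collapse per frame class.  Results are
    sorted by amino-acid length descending, ties by smaller start.  ORFs that
    hit an ambiguous codon are dropped with a warning.
    """
    if isinstance(event, BackspliceEvent):
        seq, cid = event.sequence.upper(), event.circ_id
    else:
        seq, cid = event.upper(), circ_id
    L = len(seq)
    if L < 3:
        return []
    doubled = seq * 2
    best: dict[tuple, CircORF] = {}
    for i in range(L):
        if doubled[i : i + 3] not in start_codons:
            continue
        tr = translate_circular(seq, i, max_cycles=max_cycles)
        if tr.ambiguous:
            warnings.warn(f"{cid or 'circle'}: ORF at {i} aborted on ambiguous codon")
            continue
        orf = _orf_from_walk(cid, L, i, tr)
        key = _dedup_key(orf, L)
        prev = best.get(key)
        if (
            prev is None
            or orf.aa_length > prev.aa_length
            or (orf.aa_length == prev.aa_length and orf.start < prev.start)
        ):
            best[key] = orf
    return sorted(best.values(), key=lambda o: (-o.aa_length, o.start))


# ------------------------------------------------------------------- IRES


@dataclass(frozen=True)
class IRESHit:
    """An IRES-like region, 1-based inclusive on the circle."""

    circ_id: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InputError(f"IRES hit {self.circ_id}: bad interval {self.start}-{self.end}")


def _pyrimidine_score(window: str) -> float:
    """Pyrimidine fraction + longest polypyrimidine run / window length."""
    n = len(window)
    if n == 0:
        return 0.0
    is_pyr = [b in "CT" for b in window]
    frac = sum(is_pyr) / n
    run = best = 0
    for p in is_pyr:
        run = run + 1 if p else 0
        best = max(best, run)
    return frac + best / n


def scan_ires(
    event: BackspliceEvent | str,
    circ_id: str = "",
    window: int = 150,
    step: int = 10,
    threshold: float = 0.7,
    atg_flank: int = 20,
    imported: list[tuple[int, int]] | None = None,
) -> list[IRESHit]:
    """Heuristic IRES-like region scan (or verbatim import of external calls).

    The default heuristic is an explicit proxy for an (unnamed) external IRES
    predictor: sliding windows scored by pyrimidine content plus the longest
    polypyrimidine run, requiring an AUG within ``atg_flank`` nt downstream of
    the window.  Windows above ``threshold`` merge when overlapping; merged
    regions that wrap the junction are split at the junction so every reported
    interval satisfies 1 <= start <= end <= L.  ``imported`` intervals
    (1-based inclusive) are reported verbatim, rescored with the same scorer.
    """
    if isinstance(event, BackspliceEvent):
        seq, cid = event.sequence.upper(), event.circ_id
    else:
        seq, cid = event.upper(), circ_id
    L = len(seq)
    if imported is not None:
        hits = []
        for s, e in imported:
            if not (1 <= s <= e <= L):
                raise InputError(f"imported IRES interval {s}-{e} outside circle of length {L}")
            hits.append(IRESHit(cid, s, e, _pyrimidine_score(seq[s - 1 : e])))
        return hits
    if window > L:
        warnings.warn(f"{cid or 'circle'}: IRES window {window} > circle length {L}; clipped")
        window = L
    tripled = seq * 3
    raw: list[tuple[int, int, float]] = []  # 0-based [ws, we) in doubled coords
    for ws in range(0, L, step):
        we = ws + window
        score = _pyrimidine_score(tripled[ws:we])
        if score < threshold:
            continue
        has_atg = any(
            tripled[i : i + 3] == "ATG" for i in range(we, we + atg_flank)
        )
        if not has_atg:
            continue
        raw.append((ws, we, score))
    if not raw:
        return []
    # merge overlapping windows (linear coords first, then wrap adjacency)
    raw.sort()
    merged: list[list] = [list(raw[0])]
    for ws, we, sc in raw[1:]:
        if ws <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], we)
            merged[-1][2] = max(merged[-1][2], sc)
        else:
            merged.append([ws, we, sc])
    if len(merged) > 1 and merged[-1][1] - L >= merged[0][0]:
        # last interval wraps past the junction into the first: fuse them,
        # keeping the representation [ws < L, we) with we possibly > L
        merged[0][0] = merged[-1][0]
        merged[0][1] = max(merged[0][1] + L, merged[-1][1])
        merged[0][2] = max(merged[0][2], merged[-1][2])
        merged.pop()
    hits: list[IRESHit] = []
    for ws, we, sc in merged:
        if we <= L:
            hits.append(IRESHit(cid, ws + 1, we, sc))
        else:  # wraps the junction: split into tail and head pieces
            hits.append(IRESHit(cid, ws + 1, L, sc))
            hits.append(IRESHit(cid, 1, we - L, sc))
    hits.sort(key=lambda h: (-h.score, h.start))
    return hits


# --------------------------------------------------------------- ranking


@dataclass
class CodingParams:
    """Funnel thresholds for the coding-potential screen."""

    min_len: int = 200
    max_len: int = 3000
    min_aa: int = 50
    start_window: float = 0.5  # ORF must start within this fraction of the circle
    max_cycles: int = 3
    ires_window: int = 150
    ires_step: int = 10
    ires_threshold: float = 0.7
    ires_tail_nt: int = 30  # IRES wholly inside the ORF's final this-many nt is ignored


@dataclass
class Candidate:
    """Per-circRNA funnel outcome: filter map, best ORF/IRES, rank."""

    circ_id: str
    filters: dict[str, bool]
    orf: CircORF | None
    ires: IRESHit | None
    rank: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def passes(self) -> bool:
        return all(self.filters.values())


def _interval_within_wrapped(h: IRESHit, lo: int, length: int, L: int) -> bool:
    """Is the 1-based hit wholly inside the circular interval [lo, lo+length) (0-based)?"""
    region = {(lo + i) % L for i in range(length)}
    return all(((p - 1) % L) in region for p in range(h.start, h.end + 1))


def rank_candidates(
    events: list[BackspliceEvent],
    de_table: pd.DataFrame,
    orfs: dict[str, list[CircORF]],
    ires_hits: dict[str, list[IRESHit]],
    params: CodingParams | None = None,
) -> list[Candidate]:
    """Apply the discovery funnel and rank the survivors.

    Mandatory filters, in order: differential expression + recurrence; circle
    length within [min_len, max_len]; a junction-spanning, non-rolling ORF of
    >= min_aa amino acids; such an ORF starting within the first
    ``start_window`` fraction of the circle; an IRES-like hit (or imported
    interval) not wholly inside the ORF's final ``ires_tail_nt`` nt.  Rank
    orders passers by ORF amino-acid length, ties by IRES score.
    """
    params = params or CodingParams()
    required = {"passes_de", "passes_recurrence"}
    if de_table is None or not required.issubset(de_table.columns):
        raise PipelineOrderError("rank_candidates requires the DE screen output")
    if orfs is None or ires_hits is None:
        raise PipelineOrderError("rank_candidates requires ORF and IRES stage outputs")
    candidates: list[Candidate] = []
    for ev in events:
        if ev.circ_id not in de_table.index:
            raise PipelineOrderError(f"{ev.circ_id}: missing from DE table")
        L = ev.length
        de_row = de_table.loc[ev.circ_id]
        ev_orfs = orfs.get(ev.circ_id, [])
        ev_ires = ires_hits.get(ev.circ_id, [])
        qualifying = [
            o for o in ev_orfs
            if o.spans_junction and not o.rolling_circle and o.aa_length >= params.min_aa
        ]
        positioned = [o for o in qualifying if o.start <= params.start_window * L]
        pool = positioned or qualifying or ev_orfs
        best_orf = min(pool, key=lambda o: (-o.aa_length, o.start)) if pool else None
        if best_orf is not None and best_orf.nt_length > 0 and not best_orf.rolling_circle:
            tail_lo = (best_orf.start + best_orf.nt_length - params.ires_tail_nt) % L
            valid_ires = [
                h for h in ev_ires
                if not _interval_within_wrapped(h, tail_lo, params.ires_tail_nt, L)
            ]
        else:
            valid_ires = list(ev_ires)
        best_ires = max(valid_ires, key=lambda h: h.score) if valid_ires else None
        filters = {
            "de": bool(de_row["passes_de"]) and bool(de_row["passes_recurrence"]),
            "length": params.min_len <= L <= params.max_len,
            "orf": bool(qualifying),
            "orf_position": bool(positioned),
            "ires": bool(valid_ires),
        }
        candidates.append(Candidate(ev.circ_id, filters, best_orf, best_ires))
    passers = [c for c in candidates if c.passes]
    passers.sort(
        key=lambda c: (-c.orf.aa_length, -(c.ires.score if c.ires else 0.0), c.circ_id)
    )
    for i, c in enumerate(passers, 1):
        c.rank = i
    order = {c.circ_id: (0, c.rank) for c in passers}
    candidates.sort(key=lambda c: order.get(c.circ_id, (1, 0)))
    return candidates
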
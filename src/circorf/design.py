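"""Junction-specific validation designs.

Everything a bench scientist would order after the screen calls a candidate:
epitope-tagged overexpression constructs and start-codon mutants, divergent
RT-PCR primers that only amplify across the back-splice junction, junction
siRNAs, tryptic peptides that distinguish the circle-encoded protein from its
parental protein, and TCF consensus-motif scans of promoter sequences.

Primer "thermodynamics" are deliberately simplified to GC%% and length windows
(no nearest-neighbour Tm): deterministic and testable, documented limitation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .annotate import BackspliceEvent
from .coding import CircORF, find_circular_orfs
from .errors import DesignError, InputError
from .genome import revcomp

__all__ = [
    "ConstructSpec",
    "PrimerPair",
    "PeptideEvidence",
    "FLAG_3X_NT",
    "tag_orf",
    "mutate_start",
    "design_divergent_primers",
    "classify_primer_orientation",
    "check_sirna_junction",
    "tryptic_digest",
    "junction_peptide",
    "scan_tcf_sites",
]

# nucleotide sequence encoding 3x DYKDDDDK
_FLAG_AA = "DYKDDDDK"
_AA_CODON = {"D": "GAT", "Y": "TAT", "K": "AAG"}
FLAG_3X_NT = "".join(_AA_CODON[a] for a in _FLAG_AA) * 3


@dataclass(frozen=True)
class ConstructSpec:
    """An overexpression construct: the (circular) insert sequence plus the
    protein it is expected to produce."""

    circ_id: str
    sequence: str
    variant: str  # "tagged" | "start_mutant"
    insertion_offset: int | None
    expected_protein: str | None


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    orientation: str  # "divergent" | "convergent"
    amplicon_length: int
    spans_junction: bool
    forward_start: int = -1
    reverse_end: int = -1


@dataclass(frozen=True)
class PeptideEvidence:
    """Tryptic-digest evidence distinguishing a circle-encoded protein from
    the parental protein it shares an N-terminus with."""

    protein: str
    parent_protein: str
    divergence_positions: tuple[int, ...]  # 1-based on the circle protein
    novel_suffix: str
    peptides: tuple[tuple[str, int], ...]  # (peptide, missed cleavages)
    distinguishing: tuple[str, ...]


def _best_matching_orf(construct: str, expected: str) -> CircORF | None:
    for orf in find_circular_orfs(construct):
        if orf.protein == expected:
            return orf
    return None


def tag_orf(event: BackspliceEvent, orf: CircORF, tag_nt: str = FLAG_3X_NT) -> ConstructSpec:
    """Insert an in-frame tag immediately before the ORF's stop codon.

    The insert leaves the back-splice junction and the ORF intact: re-running
    the ORF finder on the construct yields the wild-type protein plus the tag
    residues, with junction spanning preserved.  Rolling-circle ORFs have no
    stop codon to tag.
    """
    tag_nt = tag_nt.upper()
    if len(tag_nt) % 3 != 0:
        raise DesignError(f"tag length {len(tag_nt)} is not a codon multiple")
    if orf.rolling_circle or orf.stop_pos is None:
        raise DesignError(f"{event.circ_id}: rolling-circle ORF has no stop codon to tag")
    seq = event.sequence.upper()
    p = orf.stop_pos
    construct = seq[:p] + tag_nt + seq[p:]
    from Bio.Seq import Seq

    tag_residues = str(Seq(tag_nt).translate())
    expected = orf.protein + tag_residues
    found = _best_matching_orf(construct, expected)
    if found is None:
        raise DesignError(f"{event.circ_id}: tagged construct does not re-screen to protein+tag")
    return ConstructSpec(
        circ_id=event.circ_id, sequence=construct, variant="tagged",
        insertion_offset=p, expected_protein=expected,
    )


def mutate_start(
    event: BackspliceEvent, orf: CircORF, replacement: str = "CTG"
) -> ConstructSpec:
    """Abolish initiation by mutating the ORF's ATG (default ATG -> CTG).

    Verifies the substitution creates no new ATG at the mutated position and
    that no junction-spanning ORF sharing the original stop survives; if a
    downstream in-frame ATG still reaches the original stop, a warning lists
    the alternative start.
    """
    seq = event.sequence.upper()
    L = len(seq)
    s = orf.start
    start_codon = (seq * 2)[s : s + 3]
    if start_codon != "ATG":
        raise InputError(f"{event.circ_id}: ORF at {s} does not start with ATG")
    replacement = replacement.upper()
    if len(replacement) != 3 or replacement == "ATG":
        raise DesignError("start-codon replacement must be a non-ATG codon")
    doubled = list(seq * 2)
    for i, b in enumerate(replacement):
        doubled[(s + i) % L] = b
        doubled[(s + i) % L + L] = b
    mutant = "".join(doubled[:L])
    # the in-frame codon at the mutated position must no longer be a start
    assert (mutant * 2)[s : s + 3] != "ATG"
    survivors = [
        o for o in find_circular_orfs(mutant, circ_id=event.circ_id)
        if o.stop_pos == orf.stop_pos and o.spans_junction
    ]
    if survivors:
        warnings.warn(
            f"{event.circ_id}: start mutation leaves alternative start(s) at "
            + ",".join(str(o.start) for o in survivors)
            + " sharing the original stop"
        )
    return ConstructSpec(
        circ_id=event.circ_id, sequence=mutant, variant="start_mutant",
        insertion_offset=None, expected_protein=None,
    )


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def design_divergent_primers(
    event: BackspliceEvent,
    primer_min: int = 18,
    primer_max: int = 24,
    gc_min: float = 0.40,
    gc_max: float = 0.60,
    amplicon_min: int = 80,
    amplicon_max: int = 200,
    search_region: int = 120,
) -> PrimerPair:
    """Design a divergent pair whose product crosses the back-splice junction.

    The forward primer anneals in the final region of the circle, the reverse
    in the initial region, so on the circular template the amplicon runs
    through the junction (on the linear gene the primers point away from each
    other).  The best pair minimizes a simple deterministic score: distance of
    both GC fractions from 50%% plus amplicon de-centering from the junction.
    """
    seq = event.sequence.upper()
    L = len(seq)
    violations = {"amplicon": 0, "gc": 0, "length": 0}
    if L < amplicon_min:
        raise DesignError(
            f"{event.circ_id}: circle length {L} < minimum amplicon {amplicon_min} "
            "(tightest violated constraint: amplicon)"
        )
    region = min(search_region, L // 2)
    fwd_cands = []  # (start, primer, gc)
    for k in range(primer_min, primer_max + 1):
        for st in range(L - region, L - k + 1):
            p = seq[st : st + k]
            if gc_min <= _gc(p) <= gc_max:
                fwd_cands.append((st, p, _gc(p)))
            else:
                violations["gc"] += 1
    rev_cands = []  # (end_on_sense, primer, gc); reverse primer = revcomp of sense slice
    for k in range(primer_min, primer_max + 1):
        for st in range(0, region - k + 1):
            sense = seq[st : st + k]
            if gc_min <= _gc(sense) <= gc_max:
                rev_cands.append((st + k, revcomp(sense), _gc(sense)))
            else:
                violations["gc"] += 1
    best = None
    for f_start, fwd, gf in fwd_cands:
        for r_end, rev, gr in rev_cands:
            amp_len = (L - f_start) + r_end
            if not (amplicon_min <= amp_len <= amplicon_max):
                violations["amplicon"] += 1
                continue
            centering = abs((L - f_start) - r_end) / amp_len
            score = abs(gf - 0.5) + abs(gr - 0.5) + centering
            key = (score, f_start, r_end, fwd, rev)
            if best is None or key < best:
                best = key
    if best is None:
        tightest = max(violations, key=lambda k: violations[k])
        raise DesignError(
            f"{event.circ_id}: no primer pair satisfies constraints "
            f"(tightest violated constraint: {tightest})"
        )
    _, f_start, r_end, fwd, rev = best
    return PrimerPair(
        forward=fwd, reverse=rev, orientation="divergent",
        amplicon_length=(L - f_start) + r_end, spans_junction=True,
        forward_start=f_start, reverse_end=r_end,
    )


def amplicon_on_circle(event: BackspliceEvent, pair: PrimerPair) -> str:
    """The PCR product the pair yields on the circular template."""
    seq = event.sequence
    return seq[pair.forward_start :] + seq[: pair.reverse_end]


def classify_primer_orientation(pair: PrimerPair, linear_transcript: str) -> str:
    """Orient a primer pair on the linear transcript.

    Pointing toward each other (forward upstream of the reverse-binding site)
    -> convergent, amplifying the linear transcript; pointing away ->
    divergent, amplifying only across a circle's junction.
    """
    t = linear_transcript.upper()
    f_pos = t.find(pair.forward.upper())
    r_site = revcomp(pair.reverse.upper())
    r_pos = t.find(r_site)
    if f_pos < 0 or r_pos < 0:
        raise InputError("primer does not map to the transcript")
    if t.count(pair.forward.upper()) > 1 or t.count(r_site) > 1:
        raise InputError("primer maps to multiple transcript sites")
    # forward points downstream from f_pos, reverse points upstream from its
    # binding site: inward (convergent) iff the forward site lies upstream
    return "convergent" if f_pos < r_pos else "divergent"


def check_sirna_junction(
    sirna: str,
    event: BackspliceEvent,
    linear_transcript: str | None = None,
    min_overhang: int = 4,
) -> dict:
    """Junction specificity of an siRNA.

    ``junction_overlap`` is true iff the siRNA (or its reverse complement)
    occurs in the circularized sequence at an offset straddling the junction
    with at least ``min_overhang`` nt on each side; ``linear_offtarget`` is
    true iff it occurs in the linear transcript.
    """
    sirna = sirna.upper()
    if not (19 <= len(sirna) <= 23):
        raise InputError(f"siRNA length {len(sirna)} outside 19-23 nt")
    if re.search("[^ACGT]", sirna):
        raise InputError("siRNA contains ambiguity codes")
    seq = event.sequence.upper()
    L = len(seq)
    doubled = seq * 2
    n = len(sirna)
    junction = False
    for probe in (sirna, revcomp(sirna)):
        o = -1
        while True:
            o = doubled.find(probe, o + 1)
            if o < 0 or o >= L:
                break
            left = L - o
            right = o + n - L
            if left >= min_overhang and right >= min_overhang:
                junction = True
    offtarget = False
    if linear_transcript:
        t = linear_transcript.upper()
        offtarget = sirna in t or revcomp(sirna) in t
    return {"junction_overlap": junction, "linear_offtarget": offtarget}


def tryptic_digest(protein: str, max_missed: int = 0) -> list[tuple[str, int]]:
    """Trypsin digest: cleave after K or R, not before P.

    Returns (peptide, missed-cleavage count) for 0..max_missed missed
    cleavages; peptides with m missed cleavages are exactly the
    concatenations of m+1 adjacent fully cleaved fragments.
    """
    if not protein:
        return []
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    base = [protein[cuts[i] : cuts[i + 1]] for i in range(len(cuts) - 1)]
    out: list[tuple[str, int]] = []
    for m in range(max_missed + 1):
        for i in range(len(base) - m):
            out.append(("".join(base[i : i + m + 1]), m))
    return out


def junction_peptide(
    protein: str, parent_protein: str, max_missed: int = 2
) -> PeptideEvidence:
    """Tryptic peptides that distinguish the circle-encoded protein.

    Divergence positions (1-based) are indices where the circle protein
    differs from the parental N-terminal prefix, plus every position beyond
    the parent alignment; distinguishing peptides cover at least one such
    position.  The novel suffix is the maximal divergent C-terminal run.
    """
    if not protein or not parent_protein:
        raise InputError("junction_peptide: both proteins must be non-empty")
    div = [
        i + 1
        for i in range(len(protein))
        if i >= len(parent_protein) or protein[i] != parent_protein[i]
    ]
    suffix_start = len(protein)
    while suffix_start > 0 and suffix_start in div:
        suffix_start -= 1
    novel_suffix = protein[suffix_start:]
    # peptide coordinates: re-digest with positions
    peptides = tryptic_digest(protein, max_missed=max_missed)
    zero = [p for p, m in peptides if m == 0]
    pos = 0
    spans: list[tuple[str, int, int, int]] = []  # peptide, start, end, missed
    for pep, m in peptides:
        if m == 0:
            spans.append((pep, pos + 1, pos + len(pep), 0))
            pos += len(pep)
    # spans for missed-cleavage peptides via cumulative starts of base peptides
    base_starts = [s for _, s, _, _ in spans]
    for m in range(1, max_missed + 1):
        for i in range(len(zero) - m):
            pep = "".join(zero[i : i + m + 1])
            s = base_starts[i]
            spans.append((pep, s, s + len(pep) - 1, m))
    divset = set(div)
    distinguishing = tuple(
        sorted({pep for pep, s, e, _ in spans if any(s <= d <= e for d in divset)})
    )
    return PeptideEvidence(
        protein=protein,
        parent_protein=parent_protein,
        divergence_positions=tuple(div),
        novel_suffix=novel_suffix,
        peptides=tuple(peptides),
        distinguishing=distinguishing,
    )


_TCF_FWD = re.compile(r"(?=([AT][AT]CAAAG))")
_TCF_REV = re.compile(r"(?=(CTTTG[AT][AT]))")


def scan_tcf_sites(promoter_sequence: str) -> list[tuple[int, str, str]]:
    """Scan for the beta-catenin/TCF consensus 5'-(A/T)(A/T)CAAAG-3'.

    Both strands; positions are 1-based on the input sequence; N never
    matches.  Returns (position, strand, matched sequence) tuples.
    """
    seq = promoter_sequence.upper()
    if re.search("[^ACGTN]", seq):
        raise InputError("promoter sequence must be over A/C/G/T/N")
    hits = [(m.start() + 1, "+", m.group(1)) for m in _TCF_FWD.finditer(seq)]
    hits += [(m.start() + 1, "-", m.group(1)) for m in _TCF_REV.finditer(seq)]
    return sorted(hits)
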
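"""Constructs, primers, siRNAs, junction peptides, motif scans."""

import pytest
from hypothesis import given, settings, strategies as st

from circorf.annotate import BackspliceEvent
from circorf.coding import CircORF, find_circular_orfs
from circorf.design import (
    amplicon_on_circle,
    check_sirna_junction,
    classify_primer_orientation,
    design_divergent_primers,
    junction_peptide,
    mutate_start,
    scan_tcf_sites,
    tag_orf,
    tryptic_digest,
)
from circorf.errors import DesignError, InputError
from circorf.genome import revcomp


def _ev(seq, cid="c1"):
    return BackspliceEvent(cid, "chr1", 0, len(seq), "+", "exonic",
                           ((0, len(seq)),), seq)


# printed junction siRNAs of the validated circle (shifted tiling set)
SI_01 = "AGAGAGTTCAGGACAGATT"
SI_02 = "GAGAGTTCAGGACAGATTG"
SI_03 = "AGAGTTCAGGACAGATTGA"


# ------------------------------------------------------------- constructs


def test_tag_insertion_hand_example():
    ev = _ev("AAATAGATG")
    orf = find_circular_orfs(ev)[0]
    spec = tag_orf(ev, orf, "GATGAT")
    assert spec.sequence == "AAAGATGATTAGATG"
    assert spec.expected_protein == "MKDD"


def test_empty_tag_is_identity():
    ev = _ev("AAATAGATG")
    orf = find_circular_orfs(ev)[0]
    assert tag_orf(ev, orf, "").sequence == ev.sequence


def test_tag_must_be_codon_multiple():
    ev = _ev("AAATAGATG")
    orf = find_circular_orfs(ev)[0]
    with pytest.raises(DesignError, match="codon"):
        tag_orf(ev, orf, "GATGATGA")  # length 8


def test_tag_rolling_orf_is_design_error():
    ev = _ev("ATGAAAAAA")
    orf = find_circular_orfs(ev)[0]
    assert orf.rolling_circle
    with pytest.raises(DesignError, match="rolling"):
        tag_orf(ev, orf)


def test_mutate_start_abolishes_orf():
    ev = _ev("AAATAGATG")
    orf = find_circular_orfs(ev)[0]
    spec = mutate_start(ev, orf)
    assert spec.sequence == "AAATAGCTG"
    assert find_circular_orfs(spec.sequence) == []


def test_mutate_start_warns_on_alternative_shared_stop():
    # starts at 6 and 9 both wrap to the stop at 3
    ev = _ev("AAATAGATGATG")
    orf = find_circular_orfs(ev)[0]
    assert orf.start == 6
    with pytest.warns(UserWarning, match="alternative start"):
        mutate_start(ev, orf)


def test_mutate_non_atg_start_is_error():
    ev = _ev("AAATAGCTG")
    fake = CircORF("c1", 6, 0, 9, 2, True, False, 1, "LK", 3)
    with pytest.raises(InputError, match="ATG"):
        mutate_start(ev, fake)


# --------------------------------------------------------------- primers


def test_divergent_pair_amplicon_crosses_junction(analog):
    ev = _ev(analog.sequence, analog.circ_id)
    pair = design_divergent_primers(ev)
    assert pair.orientation == "divergent" and pair.spans_junction
    assert 80 <= pair.amplicon_length <= 200
    assert ev.junction_kmer(10) in amplicon_on_circle(ev, pair)


def test_primer_design_is_deterministic(analog):
    ev = _ev(analog.sequence, analog.circ_id)
    assert design_divergent_primers(ev) == design_divergent_primers(ev)


def test_primer_design_too_short_circle():
    with pytest.raises(DesignError, match="amplicon"):
        design_divergent_primers(_ev("ACGT" * 15))  # 60 nt < amplicon_min


def test_designed_pair_maps_back_divergent(analog):
    """On the linear transcript (the circle laid out linearly) the designed
    pair points outward."""
    ev = _ev(analog.sequence, analog.circ_id)
    pair = design_divergent_primers(ev)
    assert classify_primer_orientation(pair, analog.linear_seq) == "divergent"


def test_inward_pair_is_convergent(analog):
    t = analog.linear_seq
    from circorf.design import PrimerPair

    pair = PrimerPair(forward=t[100:122], reverse=revcomp(t[300:322]),
                      orientation="?", amplicon_length=222, spans_junction=False)
    assert classify_primer_orientation(pair, t) == "convergent"


def test_unmappable_primer_is_error(analog):
    from circorf.design import PrimerPair

    pair = PrimerPair(forward="T" * 20, reverse="G" * 20, orientation="?",
                      amplicon_length=0, spans_junction=False)
    with pytest.raises(InputError, match="map"):
        classify_primer_orientation(pair, analog.linear_seq)


# ---------------------------------------------------------------- siRNA


def test_sirna_junction_overlap(analog):
    ev = _ev(analog.sequence, analog.circ_id)
    L = len(ev.sequence)
    doubled = ev.sequence * 2
    junction_sirna = doubled[L - 10 : L + 9]
    res = check_sirna_junction(junction_sirna, ev, linear_transcript=analog.linear_seq)
    assert res["junction_overlap"] is True
    assert res["linear_offtarget"] is False  # the linear parent lacks the junction
    body_sirna = ev.sequence[20:39]
    res = check_sirna_junction(body_sirna, ev, linear_transcript=analog.linear_seq)
    assert res["junction_overlap"] is False
    assert res["linear_offtarget"] is True


def test_sirna_min_overhang_enforced(analog):
    ev = _ev(analog.sequence, analog.circ_id)
    L = len(ev.sequence)
    doubled = ev.sequence * 2
    skewed = doubled[L - 2 : L + 17]  # only 2 nt on the donor side
    assert check_sirna_junction(skewed, ev)["junction_overlap"] is False
    assert check_sirna_junction(skewed, ev, min_overhang=2)["junction_overlap"] is True


def test_sirna_validation():
    ev = _ev("ACGT" * 30)
    with pytest.raises(InputError):
        check_sirna_junction("ACGT", ev)  # too short
    with pytest.raises(InputError):
        check_sirna_junction("ACGTNACGTACGTACGTAC", ev)  # ambiguity code


def test_printed_sirnas_are_shifted_tiling():
    """The three published junction siRNAs tile the junction at 1-nt offsets."""
    assert SI_01[1:] == SI_02[:18]
    assert SI_02[1:] == SI_03[:18]


# -------------------------------------------------------------- peptides


def test_worked_tryptic_digest():
    assert [p for p, _ in tryptic_digest("SSRRYSEGREFRTD")] == [
        "SSR", "R", "YSEGR", "EFR", "TD",
    ]


def test_digest_respects_proline_block():
    # K before P is not cleaved
    assert [p for p, _ in tryptic_digest("AKPLK")] == ["AKPLK"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
def test_digest_identity_and_missed_cleavage_structure(protein):
    peps = tryptic_digest(protein, max_missed=2)
    zero = [p for p, m in peps if m == 0]
    assert "".join(zero) == protein
    for m in (1, 2):
        m_peps = [p for p, mm in peps if mm == m]
        for i, pep in enumerate(m_peps):
            assert pep == "".join(zero[i : i + m + 1])


def test_junction_peptide_no_divergence():
    pe = junction_peptide("MKAR", "MKARST")
    assert pe.divergence_positions == ()
    assert pe.distinguishing == ()
    assert pe.novel_suffix == ""


def test_junction_peptide_td_divergence():
    """Parent ...RSS vs circle ...RTD: divergence at the final two positions,
    and 'TD' appears in a distinguishing peptide."""
    pe = junction_peptide("MKARTD", "MKARSS")
    assert pe.divergence_positions == (5, 6)
    assert pe.novel_suffix == "TD"
    assert any("TD" in p for p in pe.distinguishing)


def test_junction_peptide_on_planted_analog(analog, genome):
    from Bio.Seq import Seq

    gene = genome.gene(analog.host_gene)
    off = genome.cds_offset(gene)
    parent = str(Seq(genome.transcript_seq(gene)[off:]).translate(to_stop=True))
    pe = junction_peptide(analog.true_orf_protein, parent)
    assert pe.divergence_positions == (294, 295)
    assert pe.novel_suffix == "TD"
    assert pe.distinguishing  # at least one junction-distinguishing peptide


# ------------------------------------------------------------ TCF motifs


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATCAAAG", [(1, "+", "ATCAAAG")]),
        ("GGCAAAG", []),
        ("CTTTGAT", [(1, "-", "CTTTGAT")]),
        ("NNCAAAG", []),  # N never matches
    ],
)
def test_tcf_consensus_examples(seq, expected):
    assert scan_tcf_sites(seq) == expected


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=7, max_size=60))
def test_tcf_hits_mirror_under_reverse_complement(seq):
    fwd = scan_tcf_sites(seq)
    rev = scan_tcf_sites(revcomp(seq))
    L = len(seq)
    mirrored = sorted(
        (L - (pos + 7) + 2, "-" if strand == "+" else "+", revcomp(site))
        for pos, strand, site in fwd
    )
    assert mirrored == rev
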
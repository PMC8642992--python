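"""Circular translation, ORF enumeration, IRES scan, funnel ranking."""

import numpy as np
import pandas as pd
import pytest

from circorf.annotate import BackspliceEvent
from circorf.coding import (
    CodingParams,
    find_circular_orfs,
    rank_candidates,
    scan_ires,
    translate_circular,
)
from circorf.errors import InputError, PipelineOrderError

from oracles import oracle_orfs, orfs_as_tuples, random_circle


def _ev(seq, cid="c1"):
    return BackspliceEvent(cid, "chr1", 0, len(seq), "+", "exonic",
                           ((0, len(seq)),), seq)


@pytest.mark.parametrize(
    "seq,start,protein,stop,rolling",
    [
        ("ATGAAATAG", 0, "MK", 6, False),  # no wrap
        ("AAATAGATG", 6, "MK", 3, False),  # stop reached after wrapping
        ("ATGAAAAAA", 0, "MKKMKKMKK", None, True),  # stop-free frame, L % 3 == 0
    ],
)
def test_translate_hand_examples(seq, start, protein, stop, rolling):
    tr = translate_circular(seq, start)
    assert tr.protein == protein
    assert tr.stop_pos == stop
    assert tr.rolling is rolling


def test_translate_validation():
    with pytest.raises(InputError):
        translate_circular("AT", 0)
    with pytest.raises(InputError):
        translate_circular("ATGAAATAG", 9)
    tr = translate_circular("ATGNNNTAG", 0)
    assert tr.ambiguous and tr.protein == "M"


def test_orf_hand_examples():
    orfs = find_circular_orfs("ATGAAATAG")
    assert len(orfs) == 1
    assert orfs[0].aa_length == 2 and not orfs[0].spans_junction
    orfs = find_circular_orfs("AAATAGATG")
    assert len(orfs) == 1
    o = orfs[0]
    assert o.aa_length == 2 and o.spans_junction and o.cycles_crossed == 1
    assert o.nt_length == 9  # includes the stop codon
    assert find_circular_orfs("AAAAAAAAA") == []  # no start codon anywhere


def test_nested_starts_collapse_to_longest_per_stop():
    # starts at 0 and 3 share the stop at 9: only the longer survives
    orfs = find_circular_orfs("ATGATGAAATAGCCC")
    assert [o.start for o in orfs] == [0]
    assert orfs[0].protein == "MMK"


@pytest.mark.parametrize("block", range(5))
def test_orf_finder_matches_exhaustive_oracle(block):
    """100 random circles per block (L <= 30) against the brute-force
    modular-walk oracle."""
    rng = np.random.default_rng(1000 + block)
    for _ in range(100):
        seq = random_circle(rng)
        assert orfs_as_tuples(find_circular_orfs(seq)) == oracle_orfs(seq), seq


def test_rotation_covariance():
    """Rotating the circle by r shifts every ORF start by -r mod L and
    preserves lengths, flags and protein strings."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        seq = random_circle(rng, min_len=6, max_len=30)
        L = len(seq)
        base_keys = {(o.start, o.aa_length, o.protein, o.rolling_circle)
                     for o in find_circular_orfs(seq)}
        for r in range(1, L):
            rotated = seq[r:] + seq[:r]
            rot_keys = {((o.start + r) % L, o.aa_length, o.protein, o.rolling_circle)
                        for o in find_circular_orfs(rotated)}
            assert rot_keys == base_keys, (seq, r)


def test_junction_protein_matches_doubled_linear_translation():
    """Every junction-spanning ORF's protein re-translates identically from
    the doubled linear sequence."""
    from Bio.Seq import Seq

    rng = np.random.default_rng(7)
    checked = 0
    while checked < 20:
        seq = random_circle(rng, min_len=9, max_len=30)
        for o in find_circular_orfs(seq):
            if not o.spans_junction or o.rolling_circle:
                continue
            doubled = seq * (2 + o.nt_length // len(seq))
            lin = doubled[o.start : o.start + o.nt_length - 3]
            assert str(Seq(lin).translate()) == o.protein
            checked += 1


def test_ires_imported_interval_verbatim():
    seq = "A" * 300
    hits = scan_ires(seq, circ_id="c", imported=[(115, 257)])
    assert len(hits) == 1
    assert (hits[0].start, hits[0].end) == (115, 257)
    assert hits[0].end - hits[0].start + 1 == 143
    with pytest.raises(InputError):
        scan_ires(seq, imported=[(0, 10)])


def test_ires_poly_a_has_no_hits():
    assert scan_ires("A" * 400) == []


def test_ires_planted_tract_is_found(coding_truth):
    """Each planted coding circle's polypyrimidine tract upstream of the ATG
    yields a hit overlapping the truth interval."""
    for t in coding_truth:
        hits = scan_ires(t.sequence, circ_id=t.circ_id)
        lo, hi = t.ires_interval
        assert any(h.start <= hi and h.end >= lo for h in hits), t.circ_id


def test_ires_window_longer_than_circle_warns():
    with pytest.warns(UserWarning, match="clipped"):
        scan_ires("CTCTCTCTCT" * 5 + "ATG" + "A" * 40, circ_id="small")


def _de_row(passes=True):
    return {"passes_de": passes, "passes_recurrence": passes}


def test_rank_candidates_missing_stage_is_pipeline_error():
    ev = _ev("ATG" + "GCA" * 80 + "TAG")
    with pytest.raises(PipelineOrderError):
        rank_candidates([ev], pd.DataFrame({"other": [1]}), {}, {})


def test_rank_candidates_filter_attribution():
    """A DE-passing circle with no ATG at all fails the ORF filter only."""
    L = 300
    seq = ("GCA" * (L // 3))  # alanine repeats: no ATG, no stop
    ev = _ev(seq, "noatg")
    de = pd.DataFrame([_de_row(True)], index=["noatg"])
    cands = rank_candidates([ev], de, {"noatg": find_circular_orfs(seq)},
                            {"noatg": []}, CodingParams())
    c = cands[0]
    assert c.filters["de"] and c.filters["length"]
    assert not c.filters["orf"] and not c.filters["orf_position"]
    assert c.rank is None


def test_rank_candidates_orders_by_orf_length(coding_truth):
    events = [_ev(t.sequence, t.circ_id) for t in coding_truth]
    de = pd.DataFrame([_de_row(True)] * len(events), index=[e.circ_id for e in events])
    orfs = {e.circ_id: find_circular_orfs(e) for e in events}
    ires = {e.circ_id: scan_ires(e) for e in events}
    cands = rank_candidates(events, de, orfs, ires)
    assert all(c.passes for c in cands)
    aa = [c.orf.aa_length for c in cands]
    assert aa == sorted(aa, reverse=True)
    assert cands[0].rank == 1


def test_planted_protein_recovered_exactly(coding_truth):
    """Round trip: the ORF finder recovers each planted protein string."""
    for t in coding_truth:
        orfs = find_circular_orfs(t.sequence, circ_id=t.circ_id)
        match = [o for o in orfs if o.protein == t.true_orf_protein]
        assert match, t.circ_id
        o = match[0]
        assert o.start == t.true_orf_start
        assert o.spans_junction and not o.rolling_circle
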
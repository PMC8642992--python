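"""Generator determinism, category allocation, counts and reads."""

import dataclasses
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from circorf.annotate import classify_circ
from circorf.errors import ConfigurationError
from circorf.quant import count_bsj_reads
from circorf.simulate import (
    DEFAULT_MIX,
    SimConfig,
    allocate_categories,
    generate_genome,
    plant_circrnas,
    simulate_counts,
    simulate_junction_reads,
)


def _genome_bytes(g, tmp_path, tag):
    fa, gff = tmp_path / f"{tag}.fa", tmp_path / f"{tag}.gff3"
    g.write_fasta(fa)
    g.write_gff3(gff)
    return fa.read_bytes() + gff.read_bytes()


def test_seed_determinism_byte_identical(tmp_path):
    a = _genome_bytes(generate_genome(SimConfig(seed=1)), tmp_path, "a")
    b = _genome_bytes(generate_genome(SimConfig(seed=1)), tmp_path, "b")
    assert a == b


def test_different_seeds_differ():
    g1 = generate_genome(SimConfig(seed=1))
    g2 = generate_genome(SimConfig(seed=2))
    assert [g.start for g in g1.genes] != [g.start for g in g2.genes]


def test_no_genes_still_emits_genome():
    g = generate_genome(SimConfig(seed=1, n_genes=0, n_coding=0))
    assert g.genes == [] and len(g.contigs) == 2


def test_contig_too_short_is_configuration_error():
    with pytest.raises(ConfigurationError, match="contig"):
        generate_genome(SimConfig(seed=1, contig_length=3000, n_genes=40))


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(seed=1, category_mix={"exonic": 1.0}).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(seed=1, planted_fc=1.0).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(seed=1, nb_dispersion=0.0).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(seed=1, n_pairs=1).validate()
    bad_mix = dict(DEFAULT_MIX)
    bad_mix["exonic"] = 0.5
    with pytest.raises(ConfigurationError, match="sum to 1"):
        SimConfig(seed=1, category_mix=bad_mix).validate()


def test_allocation_matches_printed_proportions():
    alloc = allocate_categories(DEFAULT_MIX, 100)
    assert alloc == {
        "exonic": 79, "intronic": 1, "intergenic": 4,
        "sense_overlapping": 15, "antisense": 1,
    }
    assert sum(allocate_categories(DEFAULT_MIX, 137).values()) == 137


def test_allocation_converges_chi_square():
    """At N=10,000 the realized mix must not be rejected against the target
    (chi-square goodness of fit, alpha=0.01)."""
    n = 10_000
    alloc = allocate_categories(DEFAULT_MIX, n)
    observed = [alloc[c] for c in DEFAULT_MIX]
    expected = [DEFAULT_MIX[c] * n for c in DEFAULT_MIX]
    assert stats.chisquare(observed, expected).pvalue > 0.01


def test_realized_categories_within_two(truth, sim_config):
    counts = Counter(t.true_category for t in truth)
    for cat, frac in sim_config.category_mix.items():
        assert abs(counts[cat] - frac * sim_config.n_circs) <= 2


def test_planted_categories_reclassify_identically(genome, truth):
    for t in truth[:30]:
        assert classify_circ(t.to_bsj(), genome) == t.true_category


def test_exact_number_of_coding_plants(truth, sim_config):
    assert sum(t.true_coding for t in truth) == sim_config.n_coding


def test_all_exonic_mix(genome):
    mix = {c: 0.0 for c in DEFAULT_MIX}
    mix["exonic"] = 1.0
    cfg = SimConfig(seed=3, n_circs=30, category_mix=mix)
    t, _ = plant_circrnas(generate_genome(cfg), cfg)
    assert {x.true_category for x in t} == {"exonic"}


def test_analog_structure(analog):
    """The planted analog is a 959-nt single-exon circle whose ORF starts at
    the annotated start codon, crosses the junction and gains exactly two
    novel residues ('TD') before its stop."""
    assert len(analog.sequence) == 959
    assert analog.true_orf_start == 80
    assert len(analog.true_orf_protein) == 295
    assert analog.true_orf_protein.endswith("TD")
    assert analog.ires_interval is not None
    s, e = analog.ires_interval
    assert 1 <= s <= e <= 959


def test_counts_depth_zero_all_zero(truth):
    cfg = SimConfig(seed=1, depth=0.0)
    circ, lin = simulate_counts(truth, cfg)
    assert int(circ.counts.to_numpy().sum()) == 0
    assert int(lin.counts.to_numpy().sum()) == 0


def test_counts_seed_reproducible(truth, sim_config):
    a = simulate_counts(truth, sim_config)[0].counts
    b = simulate_counts(truth, sim_config)[0].counts
    assert a.equals(b)


def test_counts_bad_dispersion(truth):
    with pytest.raises(ConfigurationError, match="dispersion"):
        simulate_counts(truth, SimConfig(seed=1, nb_dispersion=-1))


def test_mean_pair_ratio_matches_planted_fc(truth):
    """Monte-Carlo: with every circle planted at FC=4 in all pairs, the mean
    empirical tumor/normal raw-count ratio over ~2000 replicates must sit in
    [3.6, 4.4]."""
    ratios = []
    for seed in (11, 12, 13, 14):
        cfg = SimConfig(seed=seed, planted_fc=4.0)
        forced = [
            dataclasses.replace(t, true_fc_per_pair=tuple([4.0] * cfg.n_pairs))
            for t in truth
        ]
        circ, _ = simulate_counts(forced, cfg)
        for p in range(1, cfg.n_pairs + 1):
            t_col = circ.counts[f"pair{p}_tumor"].to_numpy(float)
            n_col = circ.counts[f"pair{p}_normal"].to_numpy(float)
            ratios.extend((t_col + 0.5) / (n_col + 0.5))
    assert len(ratios) >= 2000
    assert 3.6 <= np.mean(ratios) <= 4.4


def test_linear_ratio_planted_by_construction(truth, sim_config):
    """Length-normalized circ/linear rate ratios recover the planted
    [0.01, 0.06] range (per-circle mean across samples)."""
    circ, lin = simulate_counts(truth, sim_config)
    circ_rate = circ.counts.loc[lin.counts.index].div(
        circ.lengths.loc[lin.counts.index] / 1000, axis=0
    )
    lin_rate = lin.counts.div(lin.lengths / 1000, axis=0)
    per_circ = (circ_rate / lin_rate).mean(axis=1)
    assert per_circ.between(0.008, 0.075).all()


def test_reads_treated_file_has_no_linear_reads(truth, sim_config):
    untreated, treated = simulate_junction_reads(truth, sim_config)
    assert any(rid.startswith("lin|") for rid, _ in untreated)
    assert not any(rid.startswith("lin|") for rid, _ in treated)
    circ_untreated = sum(rid.startswith("circ|") for rid, _ in untreated)
    assert len(treated) >= 0.99 * circ_untreated  # >= 99% retained


def test_read_length_exceeding_circle_is_error(truth):
    with pytest.raises(ConfigurationError, match="read_length"):
        simulate_junction_reads(truth, SimConfig(seed=1, read_length=5000, anchor=10))


def test_junction_read_round_trip(genome):
    """Counting the simulated FASTQ recovers the per-circle depth within
    Poisson noise (3*sqrt(d)) for >= 95% of circles, and the treated/untreated
    circular ratio is ~1 (RNase-R resistance by construction)."""
    from circorf.annotate import reconstruct_sequence

    cfg = SimConfig(seed=5, n_circs=30, n_coding=3, n_up_noncoding=2, depth=60.0)
    g = generate_genome(cfg)
    truth, bsjs = plant_circrnas(g, cfg)
    events = [reconstruct_sequence(r, g) for r in bsjs]
    untreated, treated = simulate_junction_reads(truth, cfg)
    counts = count_bsj_reads((s for _, s in untreated), events, anchor=cfg.anchor)
    d = cfg.depth
    ok = sum(abs(counts[t.circ_id] - d) <= 3 * np.sqrt(d) for t in truth)
    assert ok >= 0.95 * len(truth)
    counts_trt = count_bsj_reads((s for _, s in treated), events, anchor=cfg.anchor)
    ratio = counts_trt.sum() / counts.sum()
    assert 0.99 <= ratio <= 1.01
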
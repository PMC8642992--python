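# circorf

Discovery and validation design for **protein-coding circular RNAs** from
back-splice junction (BSJ) calls.

Circular RNAs are covalently closed transcripts formed by back splicing: a
downstream splice donor joins an upstream acceptor, producing a circle with
no cap or polyA tail that resists RNase R digestion. A small subset of
circRNAs is translated, typically from an ORF that **crosses the back-splice
junction** — only such ORFs yield C-terminal peptides distinguishable from
the parental protein — driven by an internal ribosome entry site (IRES)
rather than a 5' cap. `circorf` implements the full desk side of a
tumor/normal coding-circRNA screen:

1. **annotate** — classify BSJ calls against a gene annotation into five
   genomic categories (exonic / intronic / intergenic / sense-overlapping /
   antisense) and reconstruct each circle's full-length sequence, registered
   so position 0 is the first base downstream of the junction;
2. **quant** — count junction-spanning reads (a read counts iff it contains
   the circle's junction 2×anchor-mer exactly), normalize to TPM
   (`tpm_i = (c_i / L_i,kb) / Σ_j (c_j / L_j,kb) × 10^6`), compute
   circ/linear abundance ratios and in-silico RNase-R retention;
3. **screen** — per-pair fold change `(t+ε)/(n+ε)`, paired two-sided t-test
   on `log2(TPM+ε)` with the decision rule **FC > 2 and p < 0.05**, a
   recurrence filter (per-pair FC > 2 in ≥ k of n pairs), and a rank-based
   ROC/Youden-cutoff biomarker statistic;
4. **coding** — enumerate AUG-initiated ORFs on the circular template
   (codons read modulo L; rolling-circle frames with no in-frame stop are
   flagged and truncated, never silently emitted), require junction
   spanning, scan for IRES-like polypyrimidine regions (or import external
   IRES calls), and rank candidates through the funnel
   *expression → length → junction ORF → ORF position → IRES*;
5. **design** — junction-specific validation designs: FLAG-tagged constructs
   (tag inserted in frame before the stop codon), start-codon mutants
   (ATG→CTG), divergent RT-PCR primers whose product crosses the BSJ,
   junction siRNAs, tryptic peptides that distinguish the circle-encoded
   protein (cleave after K/R, not before P), and TCF consensus
   (5'-(A/T)(A/T)CAAAG-3') promoter scans;
6. **simulate** — a fully deterministic synthetic-data generator (toy
   genome, planted coding circles, paired negative-binomial counts,
   junction reads with an RNase-R-treated counterpart) so the whole screen
   is testable end to end with no download.

It is aimed at computational biologists who already have BSJ calls (e.g.
from CIRI2) and want a reproducible, tested path from calls to ranked
coding candidates and orderable validation designs.

## Worked example

Run the default synthetic study (100 circles, 6 planted coding circles,
5 tumor/normal pairs):

```bash
circorf run --seed 3 --outdir run/
```

which prints (stderr) and writes under `run/report/`:

```
Discovery funnel (non-increasing):
           total: 100
              de: 7
          length: 6
             orf: 6
    orf_position: 6
            ires: 6
           final: 6

Category summary:
              exonic:   79 (79%)
            intronic:    1 (1%)
          intergenic:    4 (4%)
   sense_overlapping:   15 (15%)
           antisense:    1 (1%)

Final candidates: circ_0001, circ_0002, circ_0003, circ_0004, circ_0005, circ_0006
```

Reading: of 100 circles, 7 pass the expression screen (FC > 2, p < 0.05,
recurrent in ≥ 3 of 5 pairs), 6 survive the length/ORF/IRES filters — and
those 6 are exactly the planted coding circles. `run/design/peptides.tsv`
then lists, per candidate, the positions where the circle-encoded protein
diverges from its parental protein and the tryptic peptides covering them:

```
circ_id    divergence_positions  novel_suffix  distinguishing_peptides
circ_0001  294,295               TD            EGTKSARSIGPHAPTD,SARSIGPHAPTD,SIGPHAPTD
```

i.e. the flagship candidate is a 959-nt single-exon circle encoding a
295-aa junction-spanning protein whose final two residues ("TD") are
absent from the parental protein — the geometry of a validated coding
circRNA — and the "TD"-containing peptides are the ones to look for by
mass spectrometry. `run/design/primers.tsv` and `run/design/sirna.tsv`
hold divergent primer pairs (amplicon crosses the junction) and
junction-tiling siRNAs with their linear off-target flags.

Per-stage subcommands (`circorf simulate|annotate|quant|screen|coding`)
operate on plain files (FASTA, GFF3, BED6, FASTQ, TSV) for piecemeal use;
see `circorf --help`.

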
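# Methods

This note documents the models, conventions and numerical choices behind
`circorf`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable convention exists.

## Coordinates and circle registration

All internal coordinates are 0-based half-open; GFF3 I/O converts to the
standard's 1-based inclusive form, and BSJ input is parsed as half-open BED
(a `--one-based` flag converts 1-based starts). This convention makes a
printed genomic span such as chr16:396,147–397,106 reproduce its circle
length exactly as `end − start = 959 nt`.

Every circular sequence is registered with **position 0 immediately
downstream of the back-splice junction** (the splice-acceptor side), so the
junction lies between the last and the first base of the string. For a
plus-strand circle this is the genomic start; minus-strand circles are
reverse-complemented (exon order reversed) so the sequence reads 5'→3' on
the transcribed strand. All junction-spanning arithmetic — ORF crossing
counts, junction k-mers, siRNA overhangs, primer amplicons — follows from
this single registration.

## Category classification

A BSJ call receives exactly one of five categories by precedence:
**exonic** (both ends coincide with exon boundaries of a same-strand gene)
> **intronic** (span entirely within one intron of a same-strand gene)
> **sense_overlapping** (any same-strand gene overlap not matching the
above) > **antisense** (overlaps only opposite-strand genes) >
**intergenic**. The precedence order is a package convention — the
information-richest call wins, sense rules take priority over antisense
when both strands overlap — chosen because no published convention pins
down the boundary cases; the rule is documented rather than asserted as
anyone else's. Classification uses one representative transcript per gene.

## Junction-read counting and TPM

A read supports a circle iff it contains the junction 2×anchor-mer (last
`anchor` + first `anchor` nt of the circle; default anchor 10 nt, exact
match, no mismatches). Exact matching mirrors junction-probe logic and
keeps counting order-invariant and testable; circles sharing a junction
k-mer are reported as ambiguous. TPM is the usual per-kilobase rate
rescaled to 10^6 per sample; all-zero samples stay zero.

**Circ/linear ratio.** Per-table TPM rescaling is scale-invariant, which
makes per-feature circ/linear TPM ratios meaningful only up to a global
constant when the two tables are normalized separately (in the degenerate
case where every feature had the same true ratio r, separate-table TPM
ratios would all equal 1). The pipeline therefore computes the ratio step
on a **shared denominator** (joint normalization of circle and parental
features), which equals the length-normalized rate ratio and recovers the
generator's planted per-circle ratios directly. DE screening still
normalizes the circle table on its own denominator. Undefined ratios
(linear abundance 0) are reported as `NA`, never 0.

## Expression screen

The decision rule is |fold change| > 2 **and** p < 0.05 (both strict), with
a recurrence filter requiring per-pair fold change > 2 in at least k = 3 of
n = 5 pairs. The group test is a paired two-sided t-test on
`log2(TPM + 0.5)`. A moderated (empirical-Bayes) test would shrink
per-feature variances; the plain paired t is used instead because the
screen's operative content is the FC/p decision rule, and the t-test's
type-I error is verified by simulation (null fraction with p < 0.05 within
[0.03, 0.07] at 1,000 features). No multiple-testing correction is applied
by default — the rule is on raw p-values — with Benjamini–Hochberg
available behind a flag (via `scipy.stats.false_discovery_control`).

The ROC statistic uses the tie-corrected Mann–Whitney AUC; the reported
cutoff maximizes Youden's J = sensitivity + specificity − 1 under
"positive iff value ≥ cutoff", evaluated at observed marker values (not
midpoints, matching common clinical reporting), with J-ties broken toward
higher specificity and then toward the larger cutoff.

## Circular ORFs

`translate_circular` reads codons modulo L from any start under the
standard nuclear code, stopping at the first in-frame stop or after
`max_cycles` (default 3) full turns, in which case the walk is flagged
**rolling-circle** and its protein truncated at the cap — never emitted as
if complete. Ambiguity codes are not translated; a codon containing N
aborts that walk with a flag. `find_circular_orfs` takes every ATG on the
circle as a candidate start (near-cognate starts are deliberately out of
the default; the start-codon mutant experiment treats "the start codon" as
singular), deduplicates **stopped** walks to the longest ORF per stop
position (nested starts collapse; ties to the smaller start), and keeps
rolling walks undeduplicated — they share no stop, and collapsing them per
frame class would break rotation covariance. ORF `nt_length` includes the
stop codon; the protein excludes it — so a 295-aa junction-spanning
protein corresponds to an 888-nt ORF on a 959-nt circle. Correctness is
pinned by an exhaustive brute-force modular-walk oracle (identical output
sets on 500 random circles of length ≤ 30) and by rotation covariance
across all rotations of 100 random circles.

## IRES scan

The IRES predictor used in published screens of this kind is typically an
unnamed external tool, so the built-in scorer is an explicit **proxy**:
sliding windows (150 nt, step 10) scored by pyrimidine fraction plus the
longest polypyrimidine run divided by window length, requiring an AUG
within 20 nt downstream of the window; windows above threshold (0.7) merge
when overlapping, and merged regions that wrap the junction are split at
the junction so every reported interval is 1-based inclusive within the
circle. The threshold sits ≈ 4 standard deviations above the score of a
random window (pyrimidine fraction ≈ 0.5 ± 0.04 at 150 nt) and well below
the score of a planted 45-nt polypyrimidine tract (≈ 0.9), so false hits
on background circles are rare and planted tracts are always recovered.
Externally predicted intervals can be imported verbatim (`--ires-bed`) and
are rescored with the same scorer for ranking; import is the fidelity
option.

## Candidate funnel

Mandatory filters, in order: expression (DE + recurrence); circle length
within [200, 3000] nt; a junction-spanning, non-rolling ORF of ≥ 50 aa;
such an ORF starting within the first half of the circle (the "ORF
position" criterion in published funnels is not operationally defined
anywhere, so the start-window fraction, default 0.5, is a documented,
configurable stand-in); and an IRES hit not wholly inside the ORF's final
30 nt. Rank orders survivors by ORF amino-acid length, ties by IRES score.
Filters are evaluated with exists-semantics (a circle passes the ORF
filters if *some* qualifying ORF satisfies them), so a long out-of-window
ORF cannot mask a valid shorter one.

## Validation designs

**Tagged construct.** The tag (default 3×DYKDDDDK, configurable) is
inserted in frame immediately before the ORF's stop codon; re-screening
the construct must find a junction-spanning ORF equal to wild-type protein
plus tag residues. *Junction integrity* is defined as: the donor-side
anchor (last 10 nt) is unchanged and the acceptor side is unchanged up to
the insertion offset. For a coding circle whose stop begins within 10 nt
of the junction — which is exactly the geometry of a protein gaining two
novel residues after crossing — a literal "first 10 nt unchanged" is
impossible for *any* C-terminal tag, so the up-to-insertion form is the
strongest junction-preservation statement such constructs can satisfy.

**Start-codon mutant.** ATG→CTG by default (one transversion, cannot
create a new ATG in place); the mutant is re-screened and any surviving
junction-spanning ORF sharing the original stop is reported as a warning
naming the alternative start.

**Primers.** Divergent pairs anneal forward-in-the-tail /
reverse-in-the-head of the circle so the product crosses the junction;
constraints are primer length 18–24 nt, GC 40–60 %, amplicon 80–200 nt.
Scoring (GC distance from 50 % plus amplicon de-centering) is
deterministic; thermodynamics are deliberately simplified — no
nearest-neighbour Tm or secondary structure — a documented limitation
that keeps designs reproducible and testable. Orientation of any pair is
re-derived by mapping both primers onto the linear transcript.

**siRNAs.** A junction siRNA must occur in the circularized (doubled)
sequence straddling position 0 with ≥ 4 nt on each side; the published
junction-siRNA trios tile the junction at 1–2 nt offsets, which the
4-nt-overhang rule admits. Occurrence in the linear transcript is flagged
as an off-target.

**Peptides.** Trypsin digestion cleaves after K/R except before P, with
0–2 missed cleavages (an m-missed peptide is exactly the concatenation of
m+1 adjacent fully cleaved fragments; the 0-missed set reassembles the
protein — both are tested identities). Divergence positions are where the
circle protein differs from the parental N-terminal prefix plus every
position beyond the parent alignment; distinguishing peptides cover at
least one such position.

## Synthetic-data generator

The generator's defaults are the study conditions the screen assumes:

| parameter | default | meaning |
| --- | --- | --- |
| `n_circs` | 100 | circles planted on the toy genome |
| `category_mix` | 0.79 / 0.01 / 0.04 / 0.15 / 0.01 | exonic / intronic / intergenic / sense-overlapping / antisense, the published catalog proportions |
| `n_coding` | 6 | planted coding circles (the size of a typical shortlist) |
| `n_pairs` | 5 | paired tumor/normal samples |
| `planted_fc` | 6 | tumor/normal expectation ratio of planted up-circles |
| `noncoding_up_pairs` | 3 | non-coding up-circles are up in 3 of 5 pairs |
| `nb_dispersion` | 0.05 | shared NB dispersion (var = m + 0.05 m²) |
| `depth` | 100 | expected junction reads per circle per sample |
| `read_length` / `anchor` | 50 / 10 | read geometry |
| `linear_ratio_range` | [0.01, 0.06] | per-circle circ/linear rate ratio |

Counts are negative binomial with a shared dispersion — the standard
overdispersed count model; no generative model is published for such
screens, and library depth/variance structure here are synthetic
conventions, not reproductions. Sequencing depth of 100 junction reads per
circle and dispersion 0.05 describe a clean, deeply sequenced library.
The planted fold change of 6 represents the strong, consistently elevated
expression of a validated hit; it is set above the FC = 2 screen threshold
by enough margin that the planted recurrence pattern survives the
compression that TPM renormalization applies to up-regulated features
(with u features up f-fold among N, observed TPM fold changes shrink by
≈ (N − u + u·f)/N). Coding plants are up in all five pairs; four
non-coding plants are up in three of five, giving the funnel genuine
attrition at the expression stage.

Planted coding circles are single-exon exonic circles with a fixed layout:
ORF start `s` at the host gene's annotated start codon (s = 80 for the
959-nt flagship analog, giving a 295-aa protein; s ≈ 64 otherwise, always
with (L − s) divisible by 3 so the junction falls between codons); a
stop-free, internal-ATG-free codon body to the end of the circle; the
wrapped tail `ACA GAT TAA` encoding exactly two novel residues ("TD") and
a stop 6 nt after the junction; an in-frame TAA immediately upstream of
the ATG (so no upstream start can shadow the planted ORF under
longest-per-stop deduplication, and the start-codon mutant abolishes the
junction ORF outright); and a 45-nt polypyrimidine tract at [s−55, s−10)
as the IRES-like region. Every construction is self-validated at
generation time by re-running the ORF finder and IRES scanner; truth
proteins are computed independently by linear translation of the designed
ORF nucleotides.

Category allocation uses largest-remainder apportionment (realized
proportions exact at N = 100, chi-square-clean at N = 10,000). Parental
linear counts are scaled so each circle's length-normalized circ/linear
rate ratio is drawn once from [0.01, 0.06], with the parental transcript
tracking the circle across conditions. Junction reads all straddle the
junction with ≥ anchor nt on each side; the RNase-R-treated read set
retains every circular read and no linear reads, by construction.
Determinism: one global seed; per-stage substreams derived by fixed
offsets (`default_rng([seed, stage])`), so every stage can be regenerated
independently and all outputs are byte-identical under a fixed seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing errors and quality variation,
fragment-length and positional coverage biases, intron lariats and
alternative circular isoforms, multi-isoform genes, genes overlapping each
other, ambiguous multi-mapping reads, and biological covariance between
features. Recovery of the planted truth demonstrates the pipeline's logic
is correct under its stated model, not that the thresholds are optimal for
any particular tissue or library.

## Problem sizes

The test suite and the acceptance script run the synthetic study at its
default size (100 circles, 5 pairs, depth 100; ≈ 20,000 reads), the ORF
oracle on 500 random circles of length ≤ 30, rotation covariance on 100
circles × all rotations, DE calibration on 1,000 null and 200
partly-planted features, digests on 1,000 random proteins, and ROC checks
on 100 random 20-point instances — sizes at which every stochastic check
has comfortable margins while the whole suite runs in seconds.

## Known limitations

Alignment-based counting (SAM/BAM), multi-mapping resolution, de novo BSJ
discovery, limma's moderated statistics, nearest-neighbour primer
thermodynamics, structure-based IRES prediction and ribosome-profiling
integration are all out of scope; the module boundaries assume BSJ calls
are provided (or simulated) upstream. The clinical ROC application
(metastasis prediction) is implemented as a statistic only — no clinical
dataset ships with the package.
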
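# Methods

This note records the models, parameter choices, and numerical conventions
behind each pipeline stage, and what the synthetic-data tests do and do not
demonstrate about real data.

## Read cleaning

Adapter removal is exact-prefix, 3'-end only: a read is truncated at the
leftmost position where a prefix of the configured adapter, at least
`min_overlap` (default 6) bases long, matches exactly. Mismatch-tolerant
trimming and quality-based trimming are deliberately out of scope; the
default adapter is the Illumina TruSeq small-RNA 3' adapter and is
configurable everywhere. Filtering keeps reads of 18–25 nt with no
ambiguous base; t/rRNA contamination is removed by exact full-tag
membership in a user-supplied FASTA, since no specific contaminant
database or aligner is assumed. U is normalized to T at ingest; all
internal sequences are DNA-alphabet, and reports may print U.

Consequences worth knowing: an adapter-only read collapses to an empty
insert (then removed by the length filter), and a chance occurrence of the
6-base adapter prefix inside a genuine insert will truncate it — with a
6-mer this happens to roughly 1 in 200 random 25-mers, the standard
trade-off at this overlap length.

## Conserved-family matching

Matching is equal-length Hamming distance, at most two substitutions, no
indels — the reproducible reading of "two mismatches allowed". The family
label is derived from miRBase-style names by stripping the species prefix
and letter/number suffix, with an explicit merge table for families
conventionally reported jointly (miR156/157, miR165/166). Only 20–22 nt
tags enter the conserved search; the RPM denominator is always the full
18–25 nt clean total of the same library. A tag matching several families
counts once per family, so family RPM values can double-count a few reads;
the per-library RPM total of any single family never exceeds 10^6.

## Folding engine

Folding is a Zuker-style dynamic program over a compact nearest-neighbor
model: Watson–Crick and G:U stacking energies (a published minimal
parameter set of 36 stack values), hairpin/bulge/interior loop penalties
with Jacobson–Stockmayer extrapolation (1.75·RT·ln scaling), a linear
multibranch model (closure 3.4, branch 0.4, unpaired 0.0 kcal/mol),
hairpin loops ≥ 3 nt, interior loops capped at 30 unpaired bases (the
standard cap), and no pseudoknots, dangles, or terminal-pair penalties.
Energies are integer tenths of kcal/mol internally.

This is intentionally not the full Turner-2004 table: absolute energies
are not interchangeable with mfold or ViennaRNA output. The correctness
surface is (a) exact equivalence with an exhaustive enumeration of all
nested structures on short sequences, where the enumeration is scored by
an independent loop-decomposition function that defines the model, and
(b) the behavior of the −35 kcal/mol validity threshold, which separates
designed stems from weak ones by a wide margin in practice.

Ties are broken toward the structure with fewer base pairs — encoded
directly into the DP score (score = energy·512 + pair count, exact for
structures of < 512 pairs) — and then by a fixed traceback order, making
the returned structure deterministic. A global lexicographic-dot-bracket
tie-break is not compositional in this recursion and is not attempted.

Windows shorter than 30 nt or longer than 500 nt are rejected as
candidates rather than folded. The DP kernels are numba-compiled; a
420-nt window folds in well under a second after JIT warm-up.

## Duplex location and the five criteria

The miRNA arm is the anchored tag. The star arm is inferred from the fold
by the 2-nt 3'-overhang rule: its 5' end sits opposite the third
nucleotide from the miRNA 3' end and its 3' end extends two nucleotides
past the partner of the miRNA 5' end, with unpaired duplex ends falling
back to the nearest paired miRNA position. With the star defined this
way:

* criterion 1 compares the window MFE with −35 kcal/mol;
* criterion 2 counts miRNA positions (excluding the 2-nt 3' overhang)
  not paired into the star span; G:U is a pair, not a mismatch,
  following standard plant-miRNA annotation practice;
* criterion 3 walks consecutive paired positions and flags runs of
  unpaired bases that differ in length between the two sides — at most
  one such asymmetric bulge, of at most 2 nt, is allowed;
* criterion 4 requires miRNA:star read support of at least 5:1; when no
  star read exists the criterion is recorded as *not evaluable* and the
  candidate is reported flagged rather than silently validated, matching
  how hairpins without sequenced star strands are conventionally retained
  but annotated;
* criterion 5 requires both arms' 3' overhangs to measure exactly 2 nt
  in the realized structure.

A candidate is *valid* only if all five verdicts are affirmative.
Coordinates are 0-based half-open throughout; minus-strand candidates are
reported on the plus strand of the reported precursor sequence. A perfect
inverted repeat matches both strands and therefore yields two candidate
records; downstream summaries key hairpins by (contig, mature sequence).

Where Results-style prose elsewhere speaks of "ten criteria", the five
explicitly enumerated criteria are normative here.

## Thermodynamic descriptors

AMFE = MFE / hairpin length × 100; MFEI = |AMFE| / GC%. MFEI is reported
as a magnitude (the printed convention pairs negative AMFE with positive
MFEI); GC% comes from the precursor sequence; values are rounded only at
report time (2 decimals). GC% of zero leaves MFEI undefined and flagged.
The packaged tables carry per-row consistency flags because a few printed
rows do not satisfy the AMFE identity at two decimals (e.g. one record's
AMFE equals its MFE verbatim), indicating the printed hairpin length is
not always the length that produced the printed AMFE; flagged rows are
excluded from identity checks rather than reconciled.

## Target scoring

The expectation is a penalty sum over an ungapped antiparallel alignment:
match 0, G:U 0.5, mismatch 1.0, gap 2.0 (gaps arise only in explicitly
supplied alignments; the scanner is ungapped), all multiplied by 1.5 at
miRNA positions 2–13. This scheme is adopted from the documented defaults
of the standard plant target-prediction server, since the scoring
internals are not otherwise published; every weight is configurable. The
default reporting cutoff is 3.0; a `manual` flag carries curated pairs
above the cutoff. Translational inhibition is called when a mismatch or
gap covers miRNA position 10 or 11; cleavage otherwise. Region labels
(5' UTR / ORF / 3' UTR) require a user-supplied ORF interval table — no
ORF prediction is performed — and default to "unknown".

## Degradome confirmation

Peak categories follow the CleaveLand lineage: 4 = singleton; 0 = unique
maximum; 1 = tied maximum; 2 = above the median of non-zero counts;
3 = at or below it. The cleavage coordinate convention is the PARE
standard: the degradome tag 5' end marks the slice site opposite miRNA
positions 10–11, i.e. transcript position `site_end − 10` (0-based). A
site is confirmed when a category ≤ 2 peak lies within ±1 nt of that
position. No statistical noise model of t-plots is attempted.

## Expression

ΔCt = mean target Ct − mean internal-control Ct per condition, paired by
replicate; fold change = ΔCt(control) − ΔCt(treatment); relative
expression = 2^fold-change. "Student's t-test" is implemented as Welch's
unequal-variance test by default (a pooled-variance option exists) on the
replicate ΔCt values, because the test flavor is rarely stated; no
multiple-testing correction is applied, matching per-assay P ≤ 0.05
significance marking. Replicate counts are data-driven, not assumed. RPM
comparisons between conditions report linear and log2 ratios with a
configurable ±10% dead band for the unchanged call; a zero baseline with
non-zero treatment is reported as infinite and flagged.

## Synthetic data: what it emulates, and what it does not

The generator plants, per seed: hairpin contigs whose stem is the mature
sequence plus a 5-nt extension paired perfectly (or deliberately
imperfectly) with its reverse complement across a 10-nt loop inside 120-nt
random context; mature and star reads at 8:1 (valid) or 4:1 (ratio-decoy)
abundance with log-uniform depths of 200–2000 reads, 3' adapters attached;
filler reads drawn to an exact 18–25 nt length mixture peaking at 24 and
21 nt, the shape typical of plant small-RNA libraries; a
5% t/rRNA contaminant fraction and a handful of length/ambiguity rejects;
target transcripts containing perfect complementary sites with a 30-read
degradome peak at the expected slice position (one site's peak displaced
by 5 nt to exercise the confirmation window) over singleton background;
and Ct tables with planted treatment shifts of 0–2 cycles at 0.15-cycle
replicate noise.

MFE-decoys use AT-only stems on short contigs: the window clips at the
contig ends, because a *random* 400-nt window under this energy model
folds near −100 kcal/mol — at realistic window sizes the MFE criterion
alone rejects almost nothing, which mirrors the real pipeline, where the
duplex and read-support criteria do most of the filtering.

The generator does not emulate sequencing errors, quality-score
variation, multi-mapping ambiguity, isomiR heterogeneity, or RNA
degradation background beyond uniform singletons. Passing the recovery
tests therefore demonstrates the correctness of the pipeline's logic
under its stated assumptions, not its robustness to noisy libraries.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: ~10,000
reads per synthetic library, 23 contigs, ~45 folded candidate windows,
500-sequence oracle batches at ≤ 14 nt. These sizes were chosen so the
whole suite completes in under a minute while still exercising every code
path; all counts scale through `SyntheticConfig`.
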
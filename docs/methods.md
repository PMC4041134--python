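# Methods

This note documents the models, the numerical choices, what the synthetic
data does and does not emulate, and the design decisions taken where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and shape

mirflow is a library first: the public surface is the importable modules
plus `examples/` narrative scripts, one per capability. No console entry
points are installed — the pipeline functions (`mirflow.pipeline`) and the
examples are the interface; each stage also reads/writes the standard
text formats (FASTQ, FASTA, GFF3, TSV) so stages can be driven from shell
scripts where needed.

## Read cleaning (`preprocess`)

A raw read is the sequenced insert followed by the 3' adaptor. Filters run
in a fixed order so each discarded read has exactly one reason:
low_quality → adaptor5_contaminant → no_3prime_adaptor → no_insert →
poly_A → too_short. Kept + discarded = raw holds on every input and is
property-tested under randomized junk mixes.

Choices where the underlying procedure is conventionally under-specified:

- **Low quality**: >10% N bases, or any base below Phred 10 (both
  configurable). This is ordinary Illumina sRNA practice.
- **Poly-A**: ≥80% adenine in the insert or a terminal run of ≥10 A's —
  targets oligo-dA artifacts without discarding A-rich miRNAs.
- **Adaptor detection**: exact match of the first 8 adaptor bases, leftmost
  occurrence wins; 0 mismatches by default (1 configurable). Exactness
  keeps the per-class tallies reproducible.
- Inserts of 18–30 nt enter miRNA analysis; longer inserts remain counted
  as clean tags but are excluded downstream.

## Annotation cascade (`annotate`)

Mapping is exact full-length matching on both strands (an 18-mer seed
dictionary with verified extension; equivalence with a naive O(n·m) scan
is tested). Each tag receives exactly one category by priority —
miRNA > rRNA > tRNA > snRNA > snoRNA > exon_sense > exon_antisense >
intron_sense > intron_antisense > unannotated (configurable). The priority
is a design decision: it preserves miRNA counts and mirrors the usual
annotation cascade of sRNA pipelines. ncRNA categories are strand-aware
(sense overlap only); introns are gene/transcript spans minus exons.
Known-miRNA identification is perfect-match only — isomiRs (±1 terminal
base, internal mismatches) deliberately do not match; ties between
identical catalog entries go to the first in file order with all matches
kept in an audit field.

Tally percentages use library-wide unique-tag and total-clean-read
denominators and are formatted by exact rational arithmetic with half-up
rounding to two decimals, so printed count/total pairs reproduce exactly
regardless of binary float representation.

Coordinates are 0-based half-open internally, 1-based inclusive in GFF3
I/O; all sequences are stored in the DNA alphabet (U→T on input).

## Novel miRNA prediction (`novel`)

Parameters (Mireap-style, all configurable): mature 18–25 nt, star
reference length 20–23 nt, ≤20 genome copies, MFE ≤ −18 kcal/mol, spacing
≤ 300 nt, ≥16 duplex base pairs, bulge ≤ 4, asymmetry ≤ 4, flank 20 nt.
The star length bounds size the search window and are reported but are
not a pass/fail criterion (their exact role in the original tool is not
documented; this reading is configurable).

Procedure per anchor tag (unannotated, perfectly mapped, ≥5 reads support
by default, processed in descending abundance so the most abundant tag
defines the mature 5' end — a Dicer-cleavage proxy):

1. Two windows per hit allow the star on either side:
   [hit−flank−300−23, hit_end+flank] and [hit−flank, hit_end+flank+300+23],
   clipped to the chromosome. The window matching the mature-on-5'-arm
   orientation is folded first and the second only if the first fails —
   this halves folding cost and differs from scoring both only when both
   would pass, in which case either is an acceptable call.
2. The window is folded (ViennaRNA MFE by default); the duplex is read off
   the structure: partners of mature bases are clustered (a gap of >12 nt
   splits helices — interior loops within a genuine duplex are far
   smaller), and the cluster pairing the most mature bases is the star.
   Without clustering, stray long-range pairs in a 385-nt window inflate
   the bulge and destroy genuine candidates. The star is extended by the
   canonical 2-nt 3' overhang (always at its higher-index end, which pairs
   opposite the mature 5' end in a nested hairpin). Bulge and asymmetry
   are measured within the pairing spans, excluding the overhang.
3. The hairpin is excised — mature..star ± flank — refolded in isolation,
   and re-measured. A genuine precursor is locally stable and survives
   excision; chance window-level structure usually does not. The excised
   precursor is what gets reported and what claims the locus for
   deduplication.
4. `evaluate_candidate` applies exactly the seven threshold criteria and
   lists every violated one. Acceptance additionally requires an
   unbranched stem-loop (at most one terminal loop between the arms), per
   standard plant miRNA annotation criteria — random genomic windows
   otherwise yield duplexes that satisfy the numeric thresholds alone.
5. Counts per library sum tags whose hits fall on the accepted mature arm
   (±2 nt); hits inside an accepted precursor (either strand — the star
   arm of an accepted hairpin is not a new miRNA) are deduplicated.
   Output is locus-sorted.

Folding backends: ViennaRNA (`RNA.fold`, default) and a bundled simplified
stacking-energy dynamic program (stack −2 kcal/mol, loop penalties) for
structure-dependent logic without the thermodynamic tables. Criteria tests
use candidates designed with ≥5 kcal/mol margin so backend differences
cannot flip verdicts. Folding is O(n³) and caps input at 1000 nt.

## Differential expression (`diffexpr`)

TPM = count/total×10⁶ exactly; zero counts map to TPM 0, and only the fold
change uses a pseudo-TPM floor (0.01) — the test always runs on raw
integer counts. The exact test conditions on the count x in library 1:

p(y|x) = r^y (x+y)! / (x! y! (1+r)^{x+y+1}), r = N2/N1.

Numerics: log-gamma terms combined with logsumexp. Both tails are direct
sums — the upper tail is truncated adaptively once terms fall ~20 orders
of magnitude below the reference term (the leading term of the smallest
reported tail in the bulk routine). A float complement 1−ΣC would
catastrophically cancel for tiny upper tails; direct summation keeps
~10⁻¹³ relative accuracy, verified against exact `Fraction` arithmetic
for all x, y ≤ 200 and depth ratios ½, 1, 2.

Sidedness: the two printed tails do not by themselves define a p-value;
the package uses two-sided p = min(1, 2·min(C, D)) (one-sided available).
Note the test is inherently asymmetric in which library is conditioned
on: at equal depths the exact exchange identities are
C(x,y) = 1 − C(y,x) and D(x,y) = C(y,x) + p(x|y); p(x,y) and p(y,x) differ
by the observed point mass. Under a Poisson null at equal depths the
doubled-tail p is conservative (measured false-positive rate at 0.05 is
~4%, recomputed by the acceptance script).

Calls: DE iff |fold change| exceeds the cut-off and p < 0.01. The 1.5
cut-off is read on the linear scale (|log2fc| ≥ log₂1.5 ≈ 0.585) by
default with a log2-scale switch, since "1.5-fold" alongside a log₂ fold
change admits both readings. The <10 TPM filter removes miRNAs below
threshold in *both* libraries by default ("either" mode available). No
multiple-testing correction enters the calls; a Benjamini–Hochberg column
is emitted for downstream use.

## Target scanning (`targets`)

Gapless antiparallel scoring of every transcript window against the
miRNA: mismatch 1.0, G:U wobble 0.5, doubled at miRNA positions 2–13
(5'-anchored, 1-based), threshold 4.0 — the conventional plant
complementarity-penalty rule set. Positional constraints are optional
flags rather than hard filters: any mismatch opposite positions 10–11,
or more than one mismatch across positions 2–12; wobbles cost penalty but
do not count as mismatches for the flags. Gapless alignment keeps the
scanner exhaustively enumerable, and it is tested identical to a plain
per-window rescoring oracle. Hybridisation free energy is deliberately
not scored — the rule set here is purely positional/complementarity.

## qPCR (`qpcr`)

ΔCt per replicate, ΔΔCt as difference of condition means, RE = 2^(−ΔΔCt)
with amplification efficiency fixed at 2 and the control condition the
calibrator (RE ≡ 1). Concordance of a sequencing call: qPCR direction
agrees and the replicate ΔCts differ by a two-sample t-test at 0.05
("comparable in magnitude" is not an operational definition; direction +
significance is this package's reading, with a direction-only mode).
Rates are percentages rounded half-up to one decimal.

## Synthetic data (`simdata`)

What it emulates: two single-library conditions; planted hairpin
precursors whose mature maps uniquely; a known/novel split of the planted
catalog; log-normal baseline abundances (median ~400 TPM, σ=0.8, floored
at 50 TPM); 4 up- and 4 down-regulated miRNAs at 4-fold (|log2fc| = 2);
2×10⁵ reads per library; ncRNA decoy loci (random sequences labelled
rRNA/tRNA — synthetic stand-ins sufficient to exercise the cascade); junk
read classes at fixed fractions (poly-A 2%, no 3' adaptor 5%, insertless
2%, sub-18 2%, low-quality 1%); constant 'I' qualities with N-containing
low-quality reads; 3' adaptors appended to every clean insert.

Precursor design places the mature on the 5' arm against a
*near*-reverse-complement star (1–2 interior mismatches) — a perfect star
would plant an exact mature copy on the opposite strand — and accepts only
designs that pass every evaluator criterion with margin: ≥2 extra duplex
pairs, bulge ≤ max−2, MFE ≤ threshold −5 kcal/mol. Homopolymer-like
matures that cannot form a sufficiently stable stem are rejected with an
error.

Sampling: one categorical draw per read over {junk classes, decoys,
background, each miRNA}, so the FASTQ record count equals the depth
exactly and per-miRNA counts are Binomial(depth, p) — Poisson-like at
these depths. A negative-binomial option multiplies abundances by a
per-library Gamma variate (`dispersion`). Treatment fold changes scale
the affected miRNAs' probabilities; the decoy mass absorbs the
difference, so non-DE expectations are identical across conditions.

An optional background class (reads from a fixed pool of unannotated
genomic positions, default fraction 0) exercises the annotation cascade
and the stem-loop rejection rule; it is not part of the default study
conditions. Limitations: no base-error model, no sequence-composition
bias, no isomiRs, no degradation continuum across the transcriptome, no
biological replicates. Passing recovery tests therefore demonstrates
correctness of the pipeline's logic under its own statistical assumptions,
not robustness to real-library artifacts.

## Problem sizes in the standard runs

The test suite and acceptance script use 2×10⁵-read libraries over a
100-kb genome with 20 planted miRNAs (20 replicate seeds in the recovery
suite; 12 in the acceptance script), 10⁴ null pairs for calibration, and
x, y ≤ 200 for the oracle grid — sizes chosen so the full suite completes
in minutes on one core while every stage still operates well inside its
asymptotic regime.

## Known limitations

- Perfect-match mapping only; one mismatch anywhere drops a read (as in
  the underlying method), which understates counts for edited/isomiR loci.
- The hairpin evaluator's seven thresholds alone are permissive on random
  abundant unannotated loci; the stem-loop topology rule removes most but
  not all such candidates on real data — star-expression evidence, which
  this package does not require, is the usual next discriminator.
- The exact test assumes Poisson-like sampling within each single library;
  it is anticonservative under biological overdispersion, which a
  two-library design cannot estimate.
- ddCt assumes amplification efficiency exactly 2; no standard-curve
  correction.
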
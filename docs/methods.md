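# Methods

This note records the exact counting rules `scarsig` implements, the
conventions chosen where the published signature definitions leave room, what
the simulator does and does not emulate, and the numerical/tie-break choices
that make every result deterministic.

## Input model

Profiles are allele-specific copy-number segmentations: per segment a
chromosome interval and integer major/minor allele copies (n_maj ≥ n_min ≥ 0),
plus per-sample ploidy (genome-average copies per locus) and aberrant cell
fraction (ACF), as produced by ASCAT-style fitting of SNP-array data. Raw
array preprocessing and segmentation are out of scope; `scarsig` consumes the
segment tables.

Internally all coordinates are 0-based half-open, so segment length is simply
`end − start`; the reader converts 1-based inclusive tables on request
(`one_based=True`). Before any counting, profiles are canonicalized by fusing
abutting same-state segments. Segments separated by an uncovered gap are never
fused during canonicalization: gaps represent absent probe coverage, and all
fraction denominators (wGII, FLOH) use covered rather than annotated length so
gaps dilute nothing. Sex chromosomes are accepted on input but excluded from
every score and metric by default (allele-specific states on X/Y are ambiguous
by sex); `include_sex_chromosomes=True` overrides.

The genome annotation supplies per-chromosome length and the centromere
interval; the p-arm is `[0, centromere_start)` and the q-arm
`[centromere_end, length)`.

## Counting rules

### Major copy state

The major copy state of a chromosome is the allele-specific state covering the
greatest total length among segments with nonzero total copy number; a
chromosome carrying only homozygous deletions has none. Ties are broken by
larger covered length, then lower total copy number, then lower major-allele
count — the published definition gives no tie rule, and determinism requires
one; the choice prefers the less aberrant state.

### NtAI

For each autosome and each arm end, the outermost covered segment is counted
when all four clauses hold:

1. **telomeric** — it is the first (p-end) or last (q-end) covered segment.
   Array coverage never reaches the physical telomere, so "extends to the
   telomere" is interpreted as the outermost covered coordinate, even when
   coverage stops short of the annotated chromosome end;
2. **within one arm** — the segment lies entirely inside the p-arm or q-arm;
   segments touching or spanning the centromere interval are disqualified,
   which also guarantees a whole-chromosome imbalance is never counted;
3. **imbalanced** — n_maj ≠ n_min;
4. **deviant** — its state differs from the chromosome's major copy state.
   This is the correction for odd-ploidy chromosomes: on a uniformly (2,1)
   chromosome split by an interstitial event, both telomeric remainders still
   equal the major state and are not counted.

No minimum event size is imposed by default (none is published);
`ntai_min_size` exists for sensitivity analysis only.

### LST

Per chromosome arm (segments clipped at the centromere interval; material
inside it is dropped), segments shorter than 3 Mb are removed iteratively:
the shortest (leftmost on ties) is deleted, and if its two former neighbours
share a state they are joined into one segment spanning the removed stretch;
this repeats to a fixed point. Removal order is a documented convention —
orders can differ in which boundary position survives — and shortest-first is
used consistently by both the implementation and the test oracle. Pre-existing
uncovered gaps are only bridged when a removal makes two same-state segments
adjacent.

After smoothing, every boundary between consecutive segments of different
state counts as one transition iff both segments are ≥ 10 Mb (inclusive) and
the gap between them — nonzero only where smoothing removed material — is
strictly < 3 Mb. The transition's breakpoint is the end of the left flank.

### HRD-LOH

LOH is n_min = 0 with n_maj ≥ 1. Abutting LOH segments merge into one region
across major-allele copy changes (a (2,0)|(1,0) junction is one region).
Homozygous deletions (0,0) are total loss, not retention of one parental
allele: they neither extend a region nor fuse two regions into one, and an
uncovered gap likewise breaks a region. A region is counted iff its length is
strictly greater than 15 Mb and it does not span the entire covered extent of
its chromosome. No chromosome is excluded by default — chromosome 17, dropped
in the signature's original ovarian-cancer setting as uninformative there, is
retained because its LOH status varies across tumor types;
`loh_exclude_chroms` restores the exclusion, and scores with an exclusion are
never larger than without (monotonicity, property-tested).

### Breakpoints and overlap

Each counted event records the segmentation breakpoints delimiting it, where a
breakpoint is a position at which two covered segments abut. Chromosome ends,
coverage edges and arm-clipping boundaries are not breakpoints; a telomeric
event on a single-segment arm therefore has an empty breakpoint set, and an
LST contributes exactly one breakpoint. Pooled per signature (namespaced by
sample), the union of breakpoints is partitioned into the seven exclusive
Venn regions, reported as percentages summing to 100. Identity is exact
positional equality — sound because all three counters run on one
segmentation per sample; a bp tolerance window (single-linkage clustering per
sample and chromosome) is available for cross-platform use.

## Auxiliary metrics

- **wGII**: per autosome, the fraction of covered length whose total copy
  number differs from the baseline, then the unweighted mean across autosomes
  (small chromosomes weigh equally). The baseline is the sample ploidy rounded
  half-up (2.5 → 3); covered length is the denominator. Chromosomes with no
  coverage are excluded from the mean.
- **FLOH**: covered autosomal length with n_min = 0 over total covered
  autosomal length. (0,0) segments count toward FLOH (the minor allele is
  absent) even though they cannot extend an HRD-LOH region; FLOH consequently
  always bounds the HRD-LOH-counted fraction from above.
- **Nmut**: count of substitution, indel and dinucleotide records. Optional:
  samples without mutation data carry a missing value that propagates
  (pairwise-complete in correlations), never a silent zero.
- **DNA index / ploidy class**: ploidy divided by the expected 2; strictly
  above 1.2 classifies near-tetraploid (whole-genome doubling), otherwise
  near-diploid — an index of exactly 1.2 is near-diploid.

## Cohort statistics

QC removes samples with ACF strictly below 0.36 (0.36 exactly is retained);
missing ACF is excluded with a warning. Group summaries report 25th/50th/75th
percentiles (linear interpolation) per score. The "average ranking" of groups
ranks groups by each signature's median (average ranks on ties) and then by
the mean of the three ranks — mean-of-ranks rather than mean-of-medians,
because the three scores live on different scales; the mean-of-scores variant
is exposed as an option.

Spearman ρ uses average-rank ties and pairwise-complete missing handling, and
is undefined (NaN) below 3 pairs or at zero rank variance. The Wilcoxon
rank-sum test is two-sided; for combined n ≤ 12 the rank-sum null distribution
is enumerated exhaustively over all group assignments (valid under ties, using
the distribution's symmetry), otherwise the tie-corrected normal approximation
with continuity correction is used; the threshold is configurable. Fisher's
exact test reports the sample (cross-product) odds ratio — infinite or zero
with an off-diagonal zero cell — and the two-sided p summing hypergeometric
probabilities no larger than the observed table's. All p-values are unadjusted.

## Simulator

The generator paints a (1,1) heterozygous diploid baseline over 22 autosomes
with approximately human lengths and centromere positions (an embedded table,
deliberately approximate — the simulator makes no fine-scale positional
claims), then carves in events:

- *telomeric imbalance*: terminal (2,1) segment of 5–30 Mb behind a 4 Mb
  balanced (2,2) spacer;
- *state transition*: terminal (2,2) tail of 12–30 Mb with ≥ 10 Mb of
  baseline remaining on the arm;
- *LOH region*: interstitial (1,0) run of 16–40 Mb wrapped in 4 Mb (2,1)
  spacers, ≥ 10 Mb from arm boundaries;
- *composite* (opt-in): terminal (2,0) segment of 16–30 Mb with a ≥ 10 Mb
  flank — counted by all three signatures at one shared breakpoint, the
  stress case for the overlap analysis.

The spacers are what keeps event classes orthogonal: every junction an
implanted event creates has a sub-10 Mb flank on at least one side, so a
telomeric-imbalance or LOH event can never double as an LST; balanced LST
tails are invisible to NtAI and HRD-LOH. Placement is one event per arm,
ordered most-constrained-first (LOH → composite → LST → telomeric), with total
altered length per chromosome capped at 45% of the chromosome so the baseline
always remains the major copy state — without that cap a large terminal event
on a short chromosome could become the majority state and the NtAI deviation
clause would (correctly) stop counting it. An unplaceable request raises an
explicit error naming the constraint; events are never silently dropped. One
integer seed drives all randomness; identical seeds give byte-identical
output.

Cohorts draw per-class event counts from per-group Poisson rates (truncated
at 15 events per class, touching only the far tail at realistic rates) with
per-sample seeds derived from one master seed.

What the simulator does *not* emulate: probe-level noise, segmentation error,
subclonality or ACF-driven signal attenuation, chromothripsis-like clustered
rearrangement, and realistic co-occurrence of scar classes on one chromosome.
Passing recovery tests therefore demonstrates that the counting rules are
implemented exactly as specified and are mutually orthogonal on well-separated
events — not that the scores are robust to noisy real-world segmentation.

## Verification strategy and problem sizes

The test suite checks every counter against hand-traced toy chromosomes,
against a clause-by-clause brute-force reference on 1,000 random small
profiles (≤ 5 chromosomes, ≤ 20 segments, random states and gaps), and against
simulator ground truth over the full grid of implanted counts
{0..10}³ (1,331 profiles). Statistical kernels are checked against exhaustive
permutation and hypergeometric enumeration oracles. Property-based tests
(hypothesis, derandomized) cover canonicalization idempotence, invariance of
all scores and metrics to equal-state segment splitting, metric bounds, and
the zero-scar baseline. The cohort power check (rank-sum separation of
Poisson-rate-1 vs rate-10 groups at α = 0.01) runs 30 replicates of 40
samples per group. `scripts/acceptance.py` recomputes the headline quantities
with a 4×4×4 recovery subgrid; both the suite and the script complete in well
under a minute on one CPU.

## Known limitations

- Integer copy states are assumed; fractional/subclonal states must be
  rounded upstream.
- The centromere model is a single interval; acrocentric p-arms are treated
  like any short arm.
- LST arm assignment drops material inside the centromere interval; published
  implementations differ in how centromere-spanning segments are attributed,
  which can shift a boundary by one segment in pathological cases.
- The combined single-number HRD score built from sums of these signatures is
  intentionally out of scope, as are MSI calling, BRCA status inference and
  any treatment-response prediction.
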
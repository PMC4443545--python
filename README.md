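# scarsig

**Genomic scar signatures of homologous-recombination deficiency from
allele-specific copy-number profiles.**

Tumors that cannot repair double-strand breaks by homologous recombination
(HR) — classically through BRCA1/BRCA2 loss — accumulate characteristic gross
copy-number aberrations, or *genomic scars*, and are preferentially sensitive
to platinum agents and PARP inhibitors. Three SNP-array-based scores each
quantify one such scar class and are candidate biomarkers for HR deficiency.
`scarsig` computes all three from segmented allele-specific copy-number data
(ASCAT-style `nMajor`/`nMinor` segment tables), for people doing cohort-scale
copy-number analysis who need reproducible, testable scar scores without
touching raw array data.

## The three signatures

For a chromosome segmented into regions with integer major/minor allele copies
(n<sub>maj</sub> ≥ n<sub>min</sub> ≥ 0):

- **NtAI** — number of telomeric allelic imbalances: subtelomeric regions with
  n<sub>maj</sub> ≠ n<sub>min</sub> that extend to the telomere but do not
  cross the centromere, counted only when the region's state deviates from the
  chromosome's *major copy state* (the nonzero state covering the largest share
  of the chromosome). The deviation clause corrects a bias on odd-ploidy
  chromosomes: on a uniformly (2,1) triploid chromosome, an interstitial event
  would otherwise turn both telomeric remainders into spurious counts.
- **LST** — large-scale state transitions: after iteratively removing
  segments < 3 Mb per chromosome arm, the number of breakpoints between
  adjacent segments of different allele-specific state, both ≥ 10 Mb, with
  < 3 Mb between them.
- **HRD-LOH** — number of loss-of-heterozygosity regions (n<sub>min</sub> = 0,
  n<sub>maj</sub> ≥ 1) longer than 15 Mb but shorter than the whole
  chromosome. Chromosome 17 is included by default (it is ubiquitously lost
  only in serous ovarian cancer, so it still carries information in other
  tumor types); exclusion is available as an option.

Alongside the signatures the package computes wGII (mean per-autosome fraction
of covered length whose total copy number differs from rounded ploidy), FLOH
(LOH fraction of the covered genome), Nmut (substitutions + indels +
dinucleotide changes), and the DNA index (ploidy/2; > 1.2 → near-tetraploid),
plus cohort statistics (ACF ≥ 0.36 QC filter, group medians/quartiles with
average-rank ordering, Spearman ρ, two-sided Wilcoxon rank-sum with exact
small-sample enumeration, Fisher's exact test) and a breakpoint-level Venn
analysis of which aberrations are counted by which signatures.

A built-in simulator implants a requested number of events of each class into
a baseline diploid genome with approximately human chromosome proportions, in
shapes that exactly one signature counts (or, in composite mode, all three),
and returns the ground truth — the basis for most of the test suite.

## Worked example

Simulate a tumor with 3 telomeric imbalances, 2 state transitions and 4 large
LOH regions, then score it:

```sh
$ scarsig simulate --seed 7 --k-ntai 3 --k-lst 2 --k-loh 4 --out sim
simulated sim (seed 7): expected scores NtAI=3 LST=2 HRD-LOH=4 -> sim

$ scarsig score --segments sim/segments.tsv --annotation sim/annotation.tsv --out scored
# scarsig 0.1.0 score | LST flank >= 10.0 Mb, smoothing/gap < 3.0 Mb | HRD-LOH > 15.0 Mb, excluded: none | DNA index > 1.2 -> near-tetraploid
scored 1 sample(s) -> scored/scores.tsv

$ cat scored/scores.tsv
sample  ntai  lst  hrd_loh  wgii      floh      nmut  dna_index  ploidy_class  acf
sim     3     2    4        0.088442  0.033361        1.0        near_diploid  1.0
```

The scores recover the implanted event counts exactly. wGII = 0.088 says that
on average 8.8% of each autosome deviates from the diploid baseline; FLOH =
0.033 is the LOH fraction of the genome; the empty `nmut` column marks missing
mutation data (never silently zero). `scored/events.tsv` lists every counted
event with its breakpoints, e.g. a 21 Mb LOH region on chr12 delimited by two
junctions:

```
sim  HRD_LOH  chr12  54587495  75992467  chr12:54587495;chr12:75992467
```

Feeding those events to `scarsig overlap --events scored/events.tsv --out
venn.tsv` partitions all measured breakpoints into the seven Venn regions of
the three signatures. The same operations are available as a library
(`scarsig.score_sample`, `scarsig.simulate_profile`, ...); `scarsig cohort`
adds QC, per-group quantiles and the score correlation matrix for multi-sample
score tables.

As a library-level example of the cohort statistics, the Fisher exact test on
the p53-status-by-ploidy-class counts (1443/510 mutant/wild-type among
near-tetraploid, 1177/1513 among near-diploid tumors):

```python
>>> from scarsig import fisher_odds_ratio
>>> fisher_odds_ratio([[1443, 510], [1177, 1513]])
(3.6371282922684793, 3.94e-95)
```

— an odds ratio of 3.64: p53-mutant tumors are strongly enriched among
genome-doubled samples.

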
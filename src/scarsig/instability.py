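"""Auxiliary genome-instability metrics and ploidy classification.

These are the comparison measures run alongside the scar signatures:

wGII   weighted genome integrity index — mean over autosomes of the fraction
       of each chromosome's covered length whose total copy number differs
       from the rounded sample ploidy.
FLOH   frequency of LOH — fraction of covered autosomal length with the minor
       allele absent.
Nmut   total mutation count (substitutions + indels + dinucleotides); optional,
       missing when no mutation data exists for a sample.
DNA index and ploidy class — tumor ploidy divided by the expected diploid
       ploidy of 2; an index strictly above 1.2 classifies the genome as
       near-tetraploid (whole-genome doubling), otherwise near-diploid.

Covered length (not annotated chromosome length) is used for all denominators
so that uncovered probe gaps do not dilute the fractions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .genome import (
    GenomeAnnotation,
    MutationTable,
    SegmentProfile,
    ValidationError,
    is_sex_chromosome,
    merge_adjacent_equal,
)

__all__ = [
    "PloidyClass",
    "InstabilityMetrics",
    "wgii",
    "floh",
    "nmut",
    "classify_ploidy",
    "compute_metrics",
]

DNA_INDEX_TETRAPLOID_THRESHOLD = 1.2


class PloidyClass(str, enum.Enum):
    NEAR_DIPLOID = "near_diploid"
    NEAR_TETRAPLOID = "near_tetraploid"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class InstabilityMetrics:
    sample_id: str
    wgii: float
    floh: float
    nmut: int | None
    dna_index: float
    ploidy_class: PloidyClass


def _autosome_segments(profile: SegmentProfile):
    for seg in profile.segments:
        if not is_sex_chromosome(seg.chrom):
            yield seg


def wgii(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    *,
    ploidy_baseline: int | None = None,
) -> float:
    """Weighted genome integrity index in [0, 1].

    Per autosome, the fraction of covered length whose total copy number
    (major + minor) differs from the baseline; the index is the unweighted
    mean of those per-chromosome fractions, so small chromosomes weigh the
    same as large ones. The baseline defaults to the sample ploidy rounded
    half-up; pass ``ploidy_baseline`` to override.
    """
    profile = merge_adjacent_equal(profile)
    profile.validate_against(annotation)
    baseline = (
        ploidy_baseline
        if ploidy_baseline is not None
        else math.floor(profile.ploidy + 0.5)
    )
    covered: dict[str, int] = {}
    aberrant: dict[str, int] = {}
    for seg in _autosome_segments(profile):
        covered[seg.chrom] = covered.get(seg.chrom, 0) + seg.length
        if seg.total_copies != baseline:
            aberrant[seg.chrom] = aberrant.get(seg.chrom, 0) + seg.length
    if not covered:
        raise ValidationError(
            f"{profile.sample_id}: no covered autosomal length for wGII"
        )
    fractions = [aberrant.get(c, 0) / covered[c] for c in covered]
    return sum(fractions) / len(fractions)


def floh(profile: SegmentProfile, annotation: GenomeAnnotation) -> float:
    """Fraction of covered autosomal length in LOH (minor allele absent)."""
    profile = merge_adjacent_equal(profile)
    profile.validate_against(annotation)
    total = 0
    loh = 0
    for seg in _autosome_segments(profile):
        total += seg.length
        if seg.n_minor == 0:
            loh += seg.length
    if total == 0:
        raise ValidationError(
            f"{profile.sample_id}: no covered autosomal length for FLOH"
        )
    return loh / total


def nmut(mutations: MutationTable) -> int:
    """Total mutation count across substitutions, indels and dinucleotides."""
    return len(mutations.records)


def classify_ploidy(
    ploidy: float, threshold: float = DNA_INDEX_TETRAPLOID_THRESHOLD
) -> tuple[float, PloidyClass]:
    """DNA index (ploidy / 2) and near-diploid / near-tetraploid class.

    The near-tetraploid call requires the DNA index to be *strictly* greater
    than the threshold; an index of exactly 1.2 is near-diploid.
    """
    if ploidy <= 0:
        raise ValidationError(f"ploidy must be > 0, got {ploidy}")
    dna_index = ploidy / 2.0
    cls = (
        PloidyClass.NEAR_TETRAPLOID
        if dna_index > threshold
        else PloidyClass.NEAR_DIPLOID
    )
    return dna_index, cls


def compute_metrics(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    mutations: MutationTable | None = None,
    *,
    dna_index_threshold: float = DNA_INDEX_TETRAPLOID_THRESHOLD,
) -> InstabilityMetrics:
    """All instability metrics for one sample; Nmut is None without mutation data."""
    dna_index, cls = classify_ploidy(profile.ploidy, dna_index_threshold)
    return InstabilityMetrics(
        sample_id=profile.sample_id,
        wgii=wgii(profile, annotation),
        floh=floh(profile, annotation),
        nmut=None if mutations is None else nmut(mutations),
        dna_index=dna_index,
        ploidy_class=cls,
    )
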
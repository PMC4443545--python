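"""The three genomic-scar counting algorithms: NtAI, LST and HRD-LOH.

Each counter consumes a canonicalized :class:`~scarsig.genome.SegmentProfile`
and a :class:`~scarsig.genome.GenomeAnnotation` and returns both an integer
score and the list of counted :class:`ScarEvent` records, so that downstream
overlap analysis can ask which segmentation breakpoints each signature touched.

Definitions, in brief:

NtAI (number of telomeric allelic imbalances)
    Counts subtelomeric allelically imbalanced regions that extend to the
    telomere but do not cross the centromere. A region is counted only if its
    allele-specific state deviates from the chromosome's *major copy state* —
    the state covering the largest share of the chromosome among states with
    nonzero total copy number. This deviation clause prevents, e.g., a uniformly
    triploid (2,1) chromosome from contributing spurious telomeric events when
    an interstitial aberration elsewhere splits it in two.

LST (large-scale state transitions)
    After removing sub-3 Mb segments per chromosome arm (iterative smoothing),
    counts breakpoints between adjacent segments of different allele-specific
    state where both segments are at least 10 Mb long and the gap left by the
    smoothing is under 3 Mb.

HRD-LOH
    Counts contiguous runs of loss-of-heterozygosity (minor allele absent,
    major allele retained) longer than 15 Mb that do not span the whole
    chromosome. Chromosome 17 is *not* excluded by default: its LOH status is
    ubiquitous only in serous ovarian tumors and carries information elsewhere,
    so exclusion is opt-in via ``loh_exclude_chroms``.

All counters operate on autosomes only by default; allele-specific states on
sex chromosomes are ambiguous by sex.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .genome import (
    GenomeAnnotation,
    Segment,
    SegmentProfile,
    ValidationError,
    is_sex_chromosome,
    merge_adjacent_equal,
)

__all__ = [
    "Signature",
    "ScarEvent",
    "ScarScores",
    "ScarConfig",
    "major_copy_state",
    "count_ntai",
    "smooth_for_lst",
    "count_lst",
    "count_hrd_loh",
    "score_sample",
]


class Signature(str, enum.Enum):
    NTAI = "NTAI"
    LST = "LST"
    HRD_LOH = "HRD_LOH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ScarEvent:
    """One counted aberration and the internal breakpoints that delimit it.

    ``breakpoints`` holds only genuine segmentation junctions — positions where
    two covered segments abut. Chromosome ends and coverage edges are never
    breakpoints; a telomeric event on an arm covered by a single segment can
    therefore carry an empty breakpoint set.
    """

    sample_id: str
    signature: Signature
    chrom: str
    region_start: int
    region_end: int
    breakpoints: frozenset[tuple[str, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.region_start >= self.region_end:
            raise ValidationError(
                f"event {self.chrom}:{self.region_start}-{self.region_end}: "
                "require region_start < region_end"
            )


@dataclass(frozen=True)
class ScarScores:
    sample_id: str
    ntai: int
    lst: int
    hrd_loh: int

    def __post_init__(self) -> None:
        if min(self.ntai, self.lst, self.hrd_loh) < 0:
            raise ValidationError("scar scores must be non-negative")


@dataclass(frozen=True)
class ScarConfig:
    """Thresholds for the three counters (bp units).

    Defaults follow the signatures' source publications: 10 Mb minimum flank
    and 3 Mb smoothing / maximum gap for LST, 15 Mb minimum length for HRD-LOH
    (strictly greater than). ``ntai_min_size`` defaults to 0 — the NtAI
    definition imposes no minimum event size — and exists for sensitivity
    analysis only.
    """

    lst_min_flank: int = 10_000_000
    lst_smooth_min_keep: int = 3_000_000
    lst_max_gap: int = 3_000_000
    loh_min_len: int = 15_000_000
    loh_exclude_chroms: frozenset[str] = frozenset()
    ntai_min_size: int = 0
    include_sex_chromosomes: bool = False


DEFAULT_CONFIG = ScarConfig()


def _work_chromosomes(
    profile: SegmentProfile, annotation: GenomeAnnotation, config: ScarConfig
) -> list[str]:
    chroms = []
    for chrom in profile.chromosomes():
        if chrom not in annotation:
            raise ValidationError(f"unknown chromosome: {chrom!r}")
        if not config.include_sex_chromosomes and is_sex_chromosome(chrom):
            continue
        chroms.append(chrom)
    return chroms


def _junctions(segments: list[Segment]) -> set[int]:
    """Positions where two covered segments abut (true segmentation boundaries)."""
    return {
        a.end for a, b in zip(segments, segments[1:]) if a.end == b.start
    }


def major_copy_state(
    profile: SegmentProfile, chrom: str
) -> tuple[int, int] | None:
    """The allele-specific state covering the largest share of a chromosome.

    Only states with nonzero total copy number compete. Returns ``None`` when
    the chromosome carries nothing but homozygous deletions (or no segments).
    Ties are broken deterministically: larger covered length, then lower total
    copy number, then lower major allele count.
    """
    if chrom not in set(profile.chromosomes()):
        raise ValidationError(f"profile has no segments on chromosome {chrom!r}")
    tally: dict[tuple[int, int], int] = {}
    for seg in profile.chromosome_segments(chrom):
        if seg.total_copies > 0:
            tally[seg.state] = tally.get(seg.state, 0) + seg.length
    if not tally:
        return None
    return min(tally, key=lambda s: (-tally[s], s[0] + s[1], s[0]))


def count_ntai(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    config: ScarConfig = DEFAULT_CONFIG,
) -> tuple[int, list[ScarEvent]]:
    """Count telomeric allelic-imbalance events.

    For each autosome and each arm end, the terminal covered segment is counted
    iff it (a) is the outermost covered segment on that end, (b) lies entirely
    within one arm (segments touching or spanning the centromere interval are
    disqualified, so a whole-chromosome event is never counted), (c) is
    allelically imbalanced, and (d) deviates from the chromosome's major copy
    state.
    """
    profile = merge_adjacent_equal(profile)
    events: list[ScarEvent] = []
    for chrom in _work_chromosomes(profile, annotation, config):
        segs = profile.chromosome_segments(chrom)
        info = annotation[chrom]
        major = major_copy_state(profile, chrom)
        junctions = _junctions(segs)
        for which, seg in (("p", segs[0]), ("q", segs[-1])):
            if which == "p":
                within_arm = seg.end <= info.centromere_start
                inner = seg.end
            else:
                within_arm = seg.start >= info.centromere_end
                inner = seg.start
            if not within_arm:
                continue
            if seg.is_balanced:
                continue
            if major is not None and seg.state == major:
                continue
            if seg.length < config.ntai_min_size:
                continue
            # a single covered segment can pass the within-arm test for at
            # most one end, so p/q candidates never double-count
            bps = frozenset({(chrom, inner)} if inner in junctions else set())
            events.append(
                ScarEvent(
                    sample_id=profile.sample_id,
                    signature=Signature.NTAI,
                    chrom=chrom,
                    region_start=seg.start,
                    region_end=seg.end,
                    breakpoints=bps,
                )
            )
    return len(events), events


def smooth_for_lst(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    min_keep: int = 3_000_000,
    *,
    include_sex_chromosomes: bool = False,
) -> dict[tuple[str, str], list[Segment]]:
    """Split segments into chromosome arms and smooth away sub-``min_keep`` pieces.

    Segments are clipped to the p-arm / q-arm intervals (material inside the
    centromere interval is dropped). Then, iteratively, the shortest segment
    under ``min_keep`` is removed; if its two former neighbours share a state
    they are joined into one segment spanning the removed stretch. Runs to a
    fixed point. Returns ``{(chrom, arm): segments}`` with arm in ``{"p", "q"}``.
    """
    profile = merge_adjacent_equal(profile)
    config = replace(
        DEFAULT_CONFIG, include_sex_chromosomes=include_sex_chromosomes
    )
    arms: dict[tuple[str, str], list[Segment]] = {}
    for chrom in _work_chromosomes(profile, annotation, config):
        info = annotation[chrom]
        for arm_name, (lo, hi) in (("p", info.p_arm), ("q", info.q_arm)):
            clipped: list[Segment] = []
            for seg in profile.chromosome_segments(chrom):
                start, end = max(seg.start, lo), min(seg.end, hi)
                if start < end:
                    clipped.append(replace(seg, start=start, end=end))
            if clipped:
                arms[(chrom, arm_name)] = _smooth_arm(clipped, min_keep)
    return arms


def _smooth_arm(segs: list[Segment], min_keep: int) -> list[Segment]:
    segs = list(segs)
    while True:
        short = [
            (s.length, s.start, i)
            for i, s in enumerate(segs)
            if s.length < min_keep
        ]
        if not short:
            return segs
        _, _, i = min(short)
        del segs[i]
        if 0 < i < len(segs) and segs[i - 1].state == segs[i].state:
            segs[i - 1] = replace(segs[i - 1], end=segs[i].end)
            del segs[i]


def count_lst(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    config: ScarConfig = DEFAULT_CONFIG,
) -> tuple[int, list[ScarEvent]]:
    """Count large-scale state transitions after arm-wise smoothing.

    A transition is a boundary between consecutive same-arm segments of
    different allele-specific state, both at least ``lst_min_flank`` long, with
    an inter-segment gap (nonzero only where smoothing removed material) under
    ``lst_max_gap``. Each transition contributes exactly one breakpoint, placed
    at the end of the left flank.
    """
    arms = smooth_for_lst(
        profile,
        annotation,
        config.lst_smooth_min_keep,
        include_sex_chromosomes=config.include_sex_chromosomes,
    )
    events: list[ScarEvent] = []
    for (chrom, _arm), segs in sorted(arms.items()):
        for left, right in zip(segs, segs[1:]):
            if left.state == right.state:
                continue
            if left.length < config.lst_min_flank:
                continue
            if right.length < config.lst_min_flank:
                continue
            if right.start - left.end >= config.lst_max_gap:
                continue
            events.append(
                ScarEvent(
                    sample_id=profile.sample_id,
                    signature=Signature.LST,
                    chrom=chrom,
                    region_start=left.start,
                    region_end=right.end,
                    breakpoints=frozenset({(chrom, left.end)}),
                )
            )
    return len(events), events


def count_hrd_loh(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    config: ScarConfig = DEFAULT_CONFIG,
) -> tuple[int, list[ScarEvent]]:
    """Count LOH regions longer than ``loh_min_len`` not spanning the chromosome.

    Abutting LOH segments (minor allele 0, major allele >= 1) merge into one
    region regardless of major-allele copy changes within it. Homozygous
    deletions (0,0) neither extend a region nor fuse two regions. A region
    spanning the entire covered extent of its chromosome — whole-chromosome
    LOH — is not counted.
    """
    profile = merge_adjacent_equal(profile)
    events: list[ScarEvent] = []
    for chrom in _work_chromosomes(profile, annotation, config):
        if chrom in config.loh_exclude_chroms:
            continue
        segs = profile.chromosome_segments(chrom)
        junctions = _junctions(segs)
        covered_start, covered_end = segs[0].start, segs[-1].end
        runs: list[tuple[int, int]] = []
        run_start: int | None = None
        run_end: int | None = None
        for seg in segs:
            if seg.is_loh:
                if run_start is not None and seg.start == run_end:
                    run_end = seg.end
                else:
                    if run_start is not None:
                        runs.append((run_start, run_end))  # type: ignore[arg-type]
                    run_start, run_end = seg.start, seg.end
            else:
                if run_start is not None:
                    runs.append((run_start, run_end))  # type: ignore[arg-type]
                    run_start = run_end = None
        if run_start is not None:
            runs.append((run_start, run_end))  # type: ignore[arg-type]
        for start, end in runs:
            if end - start <= config.loh_min_len:
                continue
            if start == covered_start and end == covered_end:
                continue  # whole-chromosome LOH
            bps = frozenset(
                (chrom, pos) for pos in (start, end) if pos in junctions
            )
            events.append(
                ScarEvent(
                    sample_id=profile.sample_id,
                    signature=Signature.HRD_LOH,
                    chrom=chrom,
                    region_start=start,
                    region_end=end,
                    breakpoints=bps,
                )
            )
    return len(events), events


def score_sample(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    config: ScarConfig = DEFAULT_CONFIG,
) -> tuple[ScarScores, list[ScarEvent]]:
    """Run all three counters on one sample; scores equal per-signature event counts."""
    profile = merge_adjacent_equal(profile)
    profile.validate_against(annotation)
    ntai, ev_ntai = count_ntai(profile, annotation, config)
    lst, ev_lst = count_lst(profile, annotation, config)
    loh, ev_loh = count_hrd_loh(profile, annotation, config)
    scores = ScarScores(
        sample_id=profile.sample_id, ntai=ntai, lst=lst, hrd_loh=loh
    )
    return scores, ev_ntai + ev_lst + ev_loh
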
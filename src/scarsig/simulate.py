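"""Synthetic allele-specific segment profiles with implanted, counted scars.

The generator is the ground-truth source for the whole toolkit: it paints a
baseline heterozygous diploid genome, (1,1) everywhere, over a 22-autosome
annotation with approximately human chromosome lengths and centromeres, then
carves in a requested number of events of each scar class. Event shapes are
chosen so that — unless composite events are explicitly requested — each
implanted event is counted by exactly one signature:

* a telomeric allelic-imbalance event is a terminal (2,1) segment, 5–30 Mb,
  preceded by a 4 Mb balanced (2,2) spacer. The spacer keeps both junctions
  short-flanked on one side so the event can never double as an LST, while
  the terminal segment stays imbalanced, within one arm, and different from
  the chromosome's major copy state;
* an LST event is a single terminal state change to (2,2) (12–30 Mb tail)
  with at least 10 Mb of baseline inside it on the same arm — one breakpoint
  with two long flanks, balanced so it is invisible to NtAI and HRD-LOH;
* an HRD-LOH event is an interstitial (1,0) run of 16–40 Mb wrapped in 4 Mb
  (2,1) spacers; the spacers block LST at all four junctions and keep the run
  interstitial so NtAI ignores it;
* a composite event (``composite_events`` mode) is a terminal (2,0) segment of
  16–30 Mb with a long baseline flank: simultaneously a telomeric imbalance,
  a large-scale transition and a >15 Mb LOH region, sharing one breakpoint —
  the stress case for the overlap analysis.

Placement is one event per chromosome arm, with total altered length per
chromosome capped at 45% of the chromosome so the baseline always remains the
major copy state (otherwise the NtAI deviation clause would legitimately stop
counting a large terminal event). Unplaceable requests raise
:class:`SimulationError`; events are never silently dropped.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .genome import Chromosome, GenomeAnnotation, Segment, SegmentProfile
from .scars import ScarScores

__all__ = [
    "SimulationError",
    "SimConfig",
    "ImplantedEvent",
    "SimTruth",
    "SimSample",
    "default_annotation",
    "simulate_profile",
    "simulate_cohort",
]

MB = 1_000_000

# Approximate human autosome lengths and centromere intervals (Mb).
_HUMAN_AUTOSOMES_MB = [
    ("chr1", 249, 121, 128),
    ("chr2", 243, 91, 96),
    ("chr3", 198, 88, 94),
    ("chr4", 191, 48, 53),
    ("chr5", 181, 46, 50),
    ("chr6", 171, 59, 63),
    ("chr7", 159, 58, 62),
    ("chr8", 146, 43, 47),
    ("chr9", 141, 47, 51),
    ("chr10", 136, 38, 42),
    ("chr11", 135, 51, 56),
    ("chr12", 134, 33, 38),
    ("chr13", 115, 16, 19),
    ("chr14", 107, 15, 19),
    ("chr15", 103, 15, 20),
    ("chr16", 90, 35, 39),
    ("chr17", 81, 22, 26),
    ("chr18", 78, 15, 19),
    ("chr19", 59, 24, 28),
    ("chr20", 63, 26, 30),
    ("chr21", 48, 11, 14),
    ("chr22", 51, 13, 17),
]


class SimulationError(RuntimeError):
    """A requested event configuration cannot be placed."""


def default_annotation(n_chromosomes: int = 22) -> GenomeAnnotation:
    """Autosome-only annotation with approximately human proportions."""
    if not (1 <= n_chromosomes <= len(_HUMAN_AUTOSOMES_MB)):
        raise ValueError(f"n_chromosomes must be in 1..{len(_HUMAN_AUTOSOMES_MB)}")
    return GenomeAnnotation(
        tuple(
            Chromosome(name, length * MB, cs * MB, ce * MB)
            for name, length, cs, ce in _HUMAN_AUTOSOMES_MB[:n_chromosomes]
        )
    )


@dataclass(frozen=True)
class SimConfig:
    """Event counts, shapes and genome for one simulated profile.

    Size ranges are bp intervals, inclusive. ``spacer`` is the short buffer
    segment separating implanted events from the baseline so they cannot
    cross-trigger LST; ``arm_margin`` is the minimum baseline kept between an
    event and any arm boundary it does not intentionally touch.
    """

    seed: int
    sample_id: str = "sim"
    k_ntai: int = 0
    k_lst: int = 0
    k_loh: int = 0
    k_composite: int = 0
    composite_events: bool = False
    baseline_state: tuple[int, int] = (1, 1)
    ploidy: float = 2.0
    acf: float = 1.0
    tai_size: tuple[int, int] = (5 * MB, 30 * MB)
    lst_tail: tuple[int, int] = (12 * MB, 30 * MB)
    loh_size: tuple[int, int] = (16 * MB, 40 * MB)
    composite_size: tuple[int, int] = (16 * MB, 30 * MB)
    spacer: int = 4 * MB
    arm_margin: int = 10 * MB
    altered_budget_fraction: float = 0.45
    annotation: GenomeAnnotation = field(default_factory=default_annotation)

    def __post_init__(self) -> None:
        if min(self.k_ntai, self.k_lst, self.k_loh, self.k_composite) < 0:
            raise ValueError("event counts must be non-negative")
        if self.k_composite > 0 and not self.composite_events:
            raise ValueError("k_composite > 0 requires composite_events=True")


@dataclass(frozen=True)
class ImplantedEvent:
    """One implanted scar: its class, the scar region itself, and its state."""

    kind: str  # "tai" | "lst" | "loh" | "composite"
    chrom: str
    start: int
    end: int
    state: tuple[int, int]


@dataclass(frozen=True)
class SimTruth:
    events: tuple[ImplantedEvent, ...]
    expected: ScarScores


@dataclass(frozen=True)
class SimSample:
    group: str
    profile: SegmentProfile
    truth: SimTruth


# (kind, minimum usable arm length beyond margins) — placement order is most
# to least constrained so demanding events get the large arms first.
_PLACEMENT_ORDER = ("loh", "composite", "lst", "tai")


def simulate_profile(config: SimConfig) -> tuple[SegmentProfile, SimTruth]:
    """Deterministically generate one profile and its ground truth."""
    rng = np.random.default_rng(config.seed)
    ann = config.annotation
    arms: list[tuple[str, str, int, int]] = []
    for chrom in ann.chromosomes:
        arms.append((chrom.name, "p", *chrom.p_arm))
        arms.append((chrom.name, "q", *chrom.q_arm))
    budget = {
        c.name: int(config.altered_budget_fraction * c.length)
        for c in ann.chromosomes
    }
    altered: dict[str, int] = {c.name: 0 for c in ann.chromosomes}
    used: set[tuple[str, str]] = set()
    # painted intervals per chromosome: (start, end, state)
    paint: dict[str, list[tuple[int, int, tuple[int, int]]]] = {
        c.name: [] for c in ann.chromosomes
    }
    events: list[ImplantedEvent] = []

    requested = {
        "tai": config.k_ntai,
        "lst": config.k_lst,
        "loh": config.k_loh,
        "composite": config.k_composite if config.composite_events else 0,
    }
    for kind in _PLACEMENT_ORDER:
        for _ in range(requested[kind]):
            _place_event(kind, config, rng, arms, used, budget, altered, paint, events)

    segments = _paint_to_segments(ann, paint, config.baseline_state)
    profile = SegmentProfile(
        sample_id=config.sample_id,
        ploidy=config.ploidy,
        acf=config.acf,
        segments=tuple(segments),
    )
    profile.validate_against(ann)
    k_comp = requested["composite"]
    truth = SimTruth(
        events=tuple(events),
        expected=ScarScores(
            sample_id=config.sample_id,
            ntai=config.k_ntai + k_comp,
            lst=config.k_lst + k_comp,
            hrd_loh=config.k_loh + k_comp,
        ),
    )
    return profile, truth


def _min_span(kind: str, config: SimConfig) -> int:
    if kind == "tai":
        return config.tai_size[0] + config.spacer
    if kind == "lst":
        return config.lst_tail[0]
    if kind == "loh":
        return config.loh_size[0] + 2 * config.spacer
    return config.composite_size[0]


def _place_event(
    kind: str,
    config: SimConfig,
    rng: np.random.Generator,
    arms: list[tuple[str, str, int, int]],
    used: set[tuple[str, str]],
    budget: dict[str, int],
    altered: dict[str, int],
    paint: dict[str, list[tuple[int, int, tuple[int, int]]]],
    events: list[ImplantedEvent],
) -> None:
    min_span = _min_span(kind, config)
    margin = config.arm_margin
    # interstitial events need a margin on both sides, terminal ones on one
    need = min_span + (2 * margin if kind == "loh" else margin)
    feasible = [
        (chrom, arm, lo, hi)
        for chrom, arm, lo, hi in arms
        if (chrom, arm) not in used
        and hi - lo >= need
        and budget[chrom] - altered[chrom] >= min_span
    ]
    if not feasible:
        raise SimulationError(
            f"cannot place {kind!r} event: no free arm with >= {need} bp usable "
            f"length within the per-chromosome altered budget"
        )
    chrom, arm, lo, hi = feasible[int(rng.integers(len(feasible)))]
    arm_len = hi - lo
    room = min(arm_len - (2 * margin if kind == "loh" else margin),
               budget[chrom] - altered[chrom])

    if kind == "tai":
        size_hi = min(config.tai_size[1], room - config.spacer)
        size = int(rng.integers(config.tai_size[0], size_hi + 1))
        span = size + config.spacer
        if arm == "p":
            pieces = [(0, size, (2, 1)), (size, span, (2, 2))]
            region = (0, size)
        else:
            end = hi
            pieces = [(end - span, end - size, (2, 2)), (end - size, end, (2, 1))]
            region = (end - size, end)
        events.append(ImplantedEvent("tai", chrom, *region, state=(2, 1)))
    elif kind == "lst":
        tail_hi = min(config.lst_tail[1], room)
        tail = int(rng.integers(config.lst_tail[0], tail_hi + 1))
        span = tail
        if arm == "p":
            pieces = [(0, tail, (2, 2))]
            region = (0, tail)
        else:
            pieces = [(hi - tail, hi, (2, 2))]
            region = (hi - tail, hi)
        events.append(ImplantedEvent("lst", chrom, *region, state=(2, 2)))
    elif kind == "loh":
        size_hi = min(config.loh_size[1], room - 2 * config.spacer)
        size = int(rng.integers(config.loh_size[0], size_hi + 1))
        span = size + 2 * config.spacer
        start = int(rng.integers(lo + margin, hi - margin - span + 1))
        pieces = [
            (start, start + config.spacer, (2, 1)),
            (start + config.spacer, start + config.spacer + size, (1, 0)),
            (start + config.spacer + size, start + span, (2, 1)),
        ]
        region = (start + config.spacer, start + config.spacer + size)
        events.append(ImplantedEvent("loh", chrom, *region, state=(1, 0)))
    else:  # composite: terminal LOH+AI segment with long flanks on all sides
        size_hi = min(config.composite_size[1], room)
        size = int(rng.integers(config.composite_size[0], size_hi + 1))
        span = size
        if arm == "p":
            pieces = [(0, size, (2, 0))]
            region = (0, size)
        else:
            pieces = [(hi - size, hi, (2, 0))]
            region = (hi - size, hi)
        events.append(ImplantedEvent("composite", chrom, *region, state=(2, 0)))

    used.add((chrom, arm))
    altered[chrom] += span
    paint[chrom].extend(pieces)


def _paint_to_segments(
    annotation: GenomeAnnotation,
    paint: dict[str, list[tuple[int, int, tuple[int, int]]]],
    baseline: tuple[int, int],
) -> list[Segment]:
    segments: list[Segment] = []
    for chrom in annotation.chromosomes:
        cursor = 0
        for start, end, state in sorted(paint[chrom.name]):
            if start > cursor:
                segments.append(
                    Segment(chrom.name, cursor, start, *baseline)
                )
            segments.append(Segment(chrom.name, start, end, *state))
            cursor = end
        if cursor < chrom.length:
            segments.append(Segment(chrom.name, cursor, chrom.length, *baseline))
    return segments


def simulate_cohort(
    groups: Mapping[str, tuple[float, float, float]],
    n_per_group: int,
    seed: int,
    *,
    annotation: GenomeAnnotation | None = None,
    ploidy: float = 2.0,
    acf: float = 1.0,
    max_events_per_class: int = 15,
) -> list[SimSample]:
    """Simulate a cohort with per-group Poisson rates for each scar class.

    ``groups`` maps a group label to ``(ntai_rate, lst_rate, loh_rate)``.
    Per-class event counts are drawn Poisson and truncated at
    ``max_events_per_class`` to respect genome placement capacity (the
    truncation touches only the far upper tail at the default rates).
    Reproducible: one master seed drives all per-sample seeds.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    master = np.random.default_rng(seed)
    annotation = annotation if annotation is not None else default_annotation()
    samples: list[SimSample] = []
    for group in groups:
        rates = groups[group]
        for i in range(n_per_group):
            ks = [
                min(int(master.poisson(rate)), max_events_per_class)
                for rate in rates
            ]
            cfg = SimConfig(
                seed=int(master.integers(2**31)),
                sample_id=f"{group}_{i:04d}",
                k_ntai=ks[0],
                k_lst=ks[1],
                k_loh=ks[2],
                ploidy=ploidy,
                acf=acf,
                annotation=annotation,
            )
            profile, truth = simulate_profile(cfg)
            samples.append(SimSample(group=group, profile=profile, truth=truth))
    return samples
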
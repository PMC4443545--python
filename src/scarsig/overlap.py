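"""Cross-signature event-overlap (Venn) analysis.

Each counted scar event carries the set of internal segmentation breakpoints
that delimit it. Pooling those per signature — namespaced by sample, since all
coordinates are sample-relative — and partitioning the union into the seven
exclusive Venn regions quantifies how often the three signatures literally
count the same chromosomal break, as opposed to merely correlating at the
score level.

Breakpoint identity is exact ``(sample, chrom, position)`` equality by default,
which is well-posed because all three counters run on the same segmentation of
the same profile. A tolerance window (bp) is available for cross-platform
comparisons: positions on the same chromosome within the window are clustered
and treated as one breakpoint.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .genome import ValidationError
from .scars import ScarEvent, Signature

__all__ = ["Breakpoint", "VennFractions", "signature_breakpoints", "venn_fractions"]

#: (sample_id, chrom, position)
Breakpoint = tuple[str, str, int]

_REGIONS = (
    "ntai_only",
    "lst_only",
    "hrd_loh_only",
    "ntai_lst",
    "ntai_hrd_loh",
    "lst_hrd_loh",
    "all_three",
)


@dataclass(frozen=True)
class VennFractions:
    """The seven exclusive Venn regions as percentages of all breakpoints."""

    ntai_only: float
    lst_only: float
    hrd_loh_only: float
    ntai_lst: float
    ntai_hrd_loh: float
    lst_hrd_loh: float
    all_three: float

    def __post_init__(self) -> None:
        values = self.as_dict().values()
        if any(v < 0 for v in values):
            raise ValidationError("Venn fractions must be non-negative")
        total = sum(values)
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(f"Venn fractions must sum to 100, got {total}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _REGIONS}


def signature_breakpoints(
    events: Iterable[ScarEvent],
) -> dict[Signature, set[Breakpoint]]:
    """Union of breakpoint sets per signature, namespaced by sample."""
    out: dict[Signature, set[Breakpoint]] = {sig: set() for sig in Signature}
    for event in events:
        for chrom, pos in event.breakpoints:
            out[event.signature].add((event.sample_id, chrom, pos))
    return out


def venn_fractions(
    bp_sets: Mapping[Signature, set[Breakpoint]],
    *,
    tolerance: int = 0,
) -> VennFractions:
    """Partition the breakpoint union into the seven exclusive regions.

    Raises on an empty union. With ``tolerance > 0``, breakpoints of the same
    sample and chromosome within ``tolerance`` bp are clustered (single-linkage
    over the sorted positions) and each cluster counts once.
    """
    sets = {
        sig: set(bp_sets.get(sig, set())) for sig in Signature
    }
    if tolerance > 0:
        sets = _cluster(sets, tolerance)
    ntai, lst, loh = sets[Signature.NTAI], sets[Signature.LST], sets[Signature.HRD_LOH]
    union = ntai | lst | loh
    if not union:
        raise ValidationError("no breakpoints: Venn fractions undefined")
    counts = dict.fromkeys(_REGIONS, 0)
    for bp in union:
        membership = (bp in ntai, bp in lst, bp in loh)
        counts[_REGION_BY_MEMBERSHIP[membership]] += 1
    n = len(union)
    return VennFractions(**{k: 100.0 * v / n for k, v in counts.items()})


_REGION_BY_MEMBERSHIP = {
    (True, False, False): "ntai_only",
    (False, True, False): "lst_only",
    (False, False, True): "hrd_loh_only",
    (True, True, False): "ntai_lst",
    (True, False, True): "ntai_hrd_loh",
    (False, True, True): "lst_hrd_loh",
    (True, True, True): "all_three",
}


def _cluster(
    sets: dict[Signature, set[Breakpoint]], tolerance: int
) -> dict[Signature, set[Breakpoint]]:
    """Snap nearby positions to one representative per single-linkage cluster."""
    by_track: dict[tuple[str, str], list[int]] = {}
    for bps in sets.values():
        for sample, chrom, pos in bps:
            by_track.setdefault((sample, chrom), []).append(pos)
    representative: dict[Breakpoint, int] = {}
    for (sample, chrom), positions in by_track.items():
        positions = sorted(set(positions))
        cluster_rep = positions[0]
        prev = positions[0]
        for pos in positions:
            if pos - prev > tolerance:
                cluster_rep = pos
            representative[(sample, chrom, pos)] = cluster_rep
            prev = pos
    return {
        sig: {(s, c, representative[(s, c, p)]) for s, c, p in bps}
        for sig, bps in sets.items()
    }
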
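"""Data model and file I/O for genome annotation, allele-specific segment profiles
and mutation tables.

Coordinates are 0-based half-open internally, so ``length = end - start`` with no
off-by-one arithmetic. Readers accept ``one_based=True`` for the 1-based inclusive
dialect common in ASCAT-style segment tables and convert on ingest.

The central containers are:

``GenomeAnnotation``
    Chromosome lengths and centromere intervals. Defines the p-arm
    ``[0, centromere_start)`` and q-arm ``[centromere_end, length)`` of every
    chromosome, and hence what "telomeric" and "within one arm" mean downstream.

``SegmentProfile``
    One tumor's allele-specific copy-number segments (major/minor integer copies
    per segment) together with its ASCAT-style ploidy and aberrant cell fraction.

``MutationTable``
    A minimal per-sample mutation list (substitutions, indels, dinucleotide
    changes) used only for the Nmut metric.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "Chromosome",
    "GenomeAnnotation",
    "Segment",
    "SegmentProfile",
    "MutationRecord",
    "MutationTable",
    "VARIANT_CLASSES",
    "is_sex_chromosome",
    "read_annotation",
    "read_segments",
    "read_sample_metadata",
    "read_mutations",
    "write_segments",
    "write_annotation",
    "merge_adjacent_equal",
]


class ValidationError(ValueError):
    """An input violates a model invariant (coordinates, ordering, bounds)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


#: Accepted mutation categories for the Nmut metric.
VARIANT_CLASSES = frozenset({"substitution", "indel", "dinucleotide"})

_SEX_NAMES = frozenset({"X", "Y", "23", "24"})


def is_sex_chromosome(name: str) -> bool:
    """True for X/Y (with or without a ``chr`` prefix) and their numeric aliases."""
    stripped = name[3:] if name.lower().startswith("chr") else name
    return stripped.upper() in _SEX_NAMES


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: total length and the centromere interval, in bp."""

    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValidationError(
                f"{self.name}: require 0 < centromere_start < centromere_end < length, "
                f"got cen=[{self.centromere_start}, {self.centromere_end}) "
                f"length={self.length}"
            )

    @property
    def p_arm(self) -> tuple[int, int]:
        """Half-open p-arm interval [0, centromere_start)."""
        return (0, self.centromere_start)

    @property
    def q_arm(self) -> tuple[int, int]:
        """Half-open q-arm interval [centromere_end, length)."""
        return (self.centromere_end, self.length)


@dataclass(frozen=True)
class GenomeAnnotation:
    """Ordered collection of chromosomes; lookup by name."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("annotation must contain at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate chromosome name(s): {', '.join(dupes)}")
        object.__setattr__(
            self, "_by_name", {c.name: c for c in self.chromosomes}
        )

    def __contains__(self, name: str) -> bool:
        return name in self._by_name  # type: ignore[attr-defined]

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]  # type: ignore[attr-defined]
        except KeyError:
            raise ValidationError(f"unknown chromosome: {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def autosome_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes if not is_sex_chromosome(c.name))


@dataclass(frozen=True, order=True)
class Segment:
    """One allele-specific copy-number segment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"{self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )
        if not (self.n_major >= self.n_minor >= 0):
            raise ValidationError(
                f"{self.chrom}:{self.start}-{self.end}: require "
                f"n_major >= n_minor >= 0, got ({self.n_major}, {self.n_minor})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[int, int]:
        return (self.n_major, self.n_minor)

    @property
    def total_copies(self) -> int:
        return self.n_major + self.n_minor

    @property
    def is_balanced(self) -> bool:
        return self.n_major == self.n_minor

    @property
    def is_loh(self) -> bool:
        """Loss of heterozygosity: one parental allele absent, the other retained."""
        return self.n_minor == 0 and self.n_major >= 1


@dataclass(frozen=True)
class SegmentProfile:
    """One tumor's segments plus its ploidy and aberrant cell fraction (ACF).

    ``ploidy`` is the genome-average copies per locus from the allele-specific
    copy-number fit; ``acf`` is the estimated fraction of aberrant (tumor) cells
    in the specimen, in (0, 1].
    """

    sample_id: str
    ploidy: float
    acf: float
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValidationError(f"{self.sample_id}: ploidy must be > 0")
        if not (0 < self.acf <= 1):
            raise ValidationError(f"{self.sample_id}: acf must be in (0, 1]")
        segs = tuple(sorted(self.segments, key=lambda s: (s.chrom, s.start)))
        object.__setattr__(self, "segments", segs)
        prev: Segment | None = None
        for seg in segs:
            if prev is not None and seg.chrom == prev.chrom and seg.start < prev.end:
                raise ValidationError(
                    f"{self.sample_id} {seg.chrom}: segments overlap at "
                    f"{prev.start}-{prev.end} / {seg.start}-{seg.end}"
                )
            prev = seg

    def chromosomes(self) -> tuple[str, ...]:
        seen: OrderedDict[str, None] = OrderedDict()
        for seg in self.segments:
            seen.setdefault(seg.chrom, None)
        return tuple(seen)

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def chromosome_segments(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]

    def validate_against(self, annotation: GenomeAnnotation) -> None:
        """Check every segment lies inside its annotated chromosome."""
        for seg in self.segments:
            if seg.chrom not in annotation:
                raise ValidationError(
                    f"{self.sample_id}: unknown chromosome {seg.chrom!r}"
                )
            if seg.end > annotation[seg.chrom].length:
                raise ValidationError(
                    f"{self.sample_id} {seg.chrom}: segment {seg.start}-{seg.end} "
                    f"exceeds chromosome length {annotation[seg.chrom].length}"
                )


@dataclass(frozen=True)
class MutationRecord:
    chrom: str
    position: int
    variant_class: str

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(
                f"unknown variant_class {self.variant_class!r}; "
                f"expected one of {sorted(VARIANT_CLASSES)}"
            )


@dataclass(frozen=True)
class MutationTable:
    sample_id: str
    records: tuple[MutationRecord, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["chrom", "length", "cen_start", "cen_end"]
_SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "nMajor", "nMinor"]


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Read a BED-like annotation table: ``chrom  length  cen_start  cen_end``."""
    df = _read_tsv(path, _ANNOTATION_COLUMNS)
    chroms = []
    for row in df.itertuples(index=False):
        chroms.append(
            Chromosome(
                name=str(row.chrom),
                length=int(row.length),
                centromere_start=int(row.cen_start),
                centromere_end=int(row.cen_end),
            )
        )
    return GenomeAnnotation(tuple(chroms))


def read_sample_metadata(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a sidecar metadata table ``sample  ploidy  acf`` → {sample: (ploidy, acf)}."""
    df = _read_tsv(path, ["sample", "ploidy", "acf"])
    return {
        str(r.sample): (float(r.ploidy), float(r.acf))
        for r in df.itertuples(index=False)
    }


def read_segments(
    path: str | Path,
    annotation: GenomeAnnotation,
    *,
    one_based: bool = False,
    metadata: Mapping[str, tuple[float, float]] | None = None,
    default_ploidy: float = 2.0,
    default_acf: float = 1.0,
) -> list[SegmentProfile]:
    """Read an ASCAT-style segment table into one profile per sample.

    Expected columns: ``sample  chrom  start  end  nMajor  nMinor`` with optional
    inline ``ploidy`` and ``acf`` columns (constant within a sample). Ploidy/ACF
    may instead come from a sidecar ``metadata`` mapping; inline columns win.
    Rows of a sample may be interleaved; segments are sorted per chromosome and
    validated against ``annotation``.
    """
    df = _read_tsv(path, _SEGMENT_COLUMNS)
    has_inline = "ploidy" in df.columns and "acf" in df.columns

    per_sample: OrderedDict[str, list[Segment]] = OrderedDict()
    meta: dict[str, tuple[float, float]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            start = int(row.start)
            end = int(row.end)
            if one_based:
                start -= 1  # 1-based inclusive -> 0-based half-open
            seg = Segment(
                chrom=str(row.chrom),
                start=start,
                end=end,
                n_major=int(row.nMajor),
                n_minor=int(row.nMinor),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        sample = str(row.sample)
        per_sample.setdefault(sample, []).append(seg)
        if has_inline and sample not in meta:
            meta[sample] = (float(row.ploidy), float(row.acf))

    profiles = []
    for sample, segs in per_sample.items():
        if sample in meta:
            ploidy, acf = meta[sample]
        elif metadata is not None and sample in metadata:
            ploidy, acf = metadata[sample]
        else:
            ploidy, acf = default_ploidy, default_acf
        profile = SegmentProfile(
            sample_id=sample, ploidy=ploidy, acf=acf, segments=tuple(segs)
        )
        profile.validate_against(annotation)
        profiles.append(profile)
    return profiles


def read_mutations(path: str | Path) -> dict[str, MutationTable]:
    """Read a minimal MAF-like table ``sample  chrom  pos  variant_class``."""
    df = _read_tsv(path, ["sample", "chrom", "pos", "variant_class"])
    per_sample: OrderedDict[str, list[MutationRecord]] = OrderedDict()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = MutationRecord(
                chrom=str(row.chrom),
                position=int(row.pos),
                variant_class=str(row.variant_class),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
        per_sample.setdefault(str(row.sample), []).append(rec)
    return {
        sample: MutationTable(sample_id=sample, records=tuple(recs))
        for sample, recs in per_sample.items()
    }


def write_segments(
    profiles: Iterable[SegmentProfile],
    path: str | Path,
    *,
    include_metadata: bool = True,
) -> None:
    """Write profiles back to the segment TSV dialect (0-based half-open)."""
    rows = []
    for p in profiles:
        for s in p.segments:
            row = {
                "sample": p.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "nMajor": s.n_major,
                "nMinor": s.n_minor,
            }
            if include_metadata:
                row["ploidy"] = p.ploidy
                row["acf"] = p.acf
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": c.name,
                "length": c.length,
                "cen_start": c.centromere_start,
                "cen_end": c.centromere_end,
            }
            for c in annotation.chromosomes
        ]
    ).to_csv(path, sep="\t", index=False)


def merge_adjacent_equal(profile: SegmentProfile) -> SegmentProfile:
    """Canonicalize: fuse abutting same-chromosome segments with equal states.

    Segments separated by an uncovered gap are never fused, so total covered
    length is unchanged. Idempotent.
    """
    merged: list[Segment] = []
    for seg in profile.segments:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chrom == seg.chrom
            and prev.end == seg.start
            and prev.state == seg.state
        ):
            merged[-1] = dataclasses.replace(prev, end=seg.end)
        else:
            merged.append(seg)
    return dataclasses.replace(profile, segments=tuple(merged))


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s): {', '.join(missing)}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df
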
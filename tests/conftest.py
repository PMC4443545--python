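import pytest

from scarsig import Chromosome, GenomeAnnotation, Segment, SegmentProfile

MB = 1_000_000


def mb(x: float) -> int:
    return int(x * MB)


def seg(chrom, start, end, n_major, n_minor) -> Segment:
    """Segment with Mb coordinates, for readable toy genomes."""
    return Segment(chrom, mb(start), mb(end), n_major, n_minor)


def profile(segments, sample_id="toy", ploidy=2.0, acf=1.0) -> SegmentProfile:
    return SegmentProfile(
        sample_id=sample_id, ploidy=ploidy, acf=acf, segments=tuple(segments)
    )


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """chr1: 100 Mb, cen 45-55; chr2: 80 Mb, cen 35-45; chr3: 100 Mb, cen 45-55."""
    return GenomeAnnotation(
        (
            Chromosome("chr1", mb(100), mb(45), mb(55)),
            Chromosome("chr2", mb(80), mb(35), mb(45)),
            Chromosome("chr3", mb(100), mb(45), mb(55)),
        )
    )
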
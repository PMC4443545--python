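"""Hand-traced toy chromosomes, properties, and oracle equivalence for the
three scar counters."""

import random

import pytest

from scarsig import (
    Chromosome,
    GenomeAnnotation,
    ScarConfig,
    Segment,
    SegmentProfile,
    ValidationError,
    count_hrd_loh,
    count_lst,
    count_ntai,
    major_copy_state,
    score_sample,
    smooth_for_lst,
)

from .conftest import mb, profile, seg
from .reference_impl import ref_hrd_loh, ref_lst, ref_major_state, ref_ntai


class TestMajorCopyState:
    def test_longest_state_wins(self):
        p = profile([seg("chr1", 0, 60, 1, 1), seg("chr1", 60, 100, 2, 1)])
        assert major_copy_state(p, "chr1") == (1, 1)

    def test_single_state(self):
        p = profile([seg("chr1", 0, 100, 2, 1)])
        assert major_copy_state(p, "chr1") == (2, 1)

    def test_exact_tie_prefers_lower_total_copy_number(self):
        p = profile([seg("chr1", 0, 50, 1, 1), seg("chr1", 50, 100, 2, 1)])
        assert major_copy_state(p, "chr1") == (1, 1)

    def test_total_loss_has_no_major_state(self):
        p = profile([seg("chr1", 0, 100, 0, 0)])
        assert major_copy_state(p, "chr1") is None

    def test_unknown_chromosome_errors(self):
        p = profile([seg("chr1", 0, 100, 1, 1)])
        with pytest.raises(ValidationError):
            major_copy_state(p, "chr9")


class TestNtai:
    def test_q_telomeric_imbalance_deviating_from_major_state(self, toy_annotation):
        p = profile([seg("chr1", 0, 60, 1, 1), seg("chr1", 60, 100, 2, 1)])
        count, events = count_ntai(p, toy_annotation)
        assert count == 1
        (event,) = events
        assert event.chrom == "chr1"
        assert event.breakpoints == frozenset({("chr1", mb(60))})

    def test_whole_chromosome_imbalance_spans_centromere(self, toy_annotation):
        p = profile([seg("chr1", 0, 100, 2, 1)])
        assert count_ntai(p, toy_annotation)[0] == 0

    def test_triploid_chromosome_correction(self, toy_annotation):
        # both telomeric (2,1) segments equal the chromosome's major copy
        # state, so the interstitial event creates no telomeric counts
        p = profile(
            [seg("chr1", 0, 40, 2, 1), seg("chr1", 40, 60, 2, 2),
             seg("chr1", 60, 100, 2, 1)]
        )
        assert count_ntai(p, toy_annotation)[0] == 0

    def test_balanced_genome_scores_zero(self, toy_annotation):
        p = profile(
            [seg("chr1", 0, 100, 1, 1), seg("chr2", 0, 80, 1, 1),
             seg("chr3", 0, 100, 1, 1)]
        )
        assert count_ntai(p, toy_annotation)[0] == 0

    def test_coverage_stopping_short_of_telomere_still_counts(self, toy_annotation):
        # array coverage never reaches the physical telomere; the outermost
        # covered segment is the telomeric candidate
        p = profile([seg("chr1", 2, 60, 1, 1), seg("chr1", 60, 98, 2, 1)])
        assert count_ntai(p, toy_annotation)[0] == 1

    def test_p_telomeric_event_counts(self, toy_annotation):
        p = profile([seg("chr1", 0, 40, 2, 1), seg("chr1", 40, 100, 1, 1)])
        count, (event,) = count_ntai(p, toy_annotation)
        assert count == 1
        assert event.breakpoints == frozenset({("chr1", mb(40))})

    def test_min_size_filter_is_off_by_default(self, toy_annotation):
        p = profile([seg("chr1", 0, 99, 1, 1), seg("chr1", 99, 100, 2, 1)])
        assert count_ntai(p, toy_annotation)[0] == 1
        cfg = ScarConfig(ntai_min_size=mb(5))
        assert count_ntai(p, toy_annotation, cfg)[0] == 0


class TestLstSmoothing:
    def test_sub_3mb_interruption_is_absorbed(self, toy_annotation):
        p = profile(
            [seg("chr1", 55, 79.5, 1, 1), seg("chr1", 79.5, 81.5, 3, 1),
             seg("chr1", 81.5, 100, 1, 1)]
        )
        arms = smooth_for_lst(p, toy_annotation)
        assert [(s.start, s.end, s.state) for s in arms[("chr1", "q")]] == [
            (mb(55), mb(100), (1, 1))
        ]

    def test_segments_at_or_above_3mb_are_kept(self, toy_annotation):
        p = profile([seg("chr1", 55, 80, 1, 1), seg("chr1", 80, 100, 2, 1)])
        arms = smooth_for_lst(p, toy_annotation)
        assert len(arms[("chr1", "q")]) == 2

    def test_single_segment_arm_unchanged(self, toy_annotation):
        p = profile([seg("chr1", 55, 100, 2, 1)])
        arms = smooth_for_lst(p, toy_annotation)
        assert [(s.start, s.end) for s in arms[("chr1", "q")]] == [(mb(55), mb(100))]

    def test_centromere_spanning_segment_is_split_between_arms(self, toy_annotation):
        p = profile([seg("chr1", 0, 100, 1, 1)])
        arms = smooth_for_lst(p, toy_annotation)
        assert [(s.start, s.end) for s in arms[("chr1", "p")]] == [(0, mb(45))]
        assert [(s.start, s.end) for s in arms[("chr1", "q")]] == [(mb(55), mb(100))]


class TestLst:
    def test_transition_with_two_long_flanks(self, toy_annotation):
        p = profile([seg("chr1", 55, 80, 1, 1), seg("chr1", 80, 100, 2, 1)])
        count, (event,) = count_lst(p, toy_annotation)
        assert count == 1
        assert event.breakpoints == frozenset({("chr1", mb(80))})

    def test_short_middle_segment_blocks_both_boundaries(self, toy_annotation):
        # 8 Mb middle: too long to smooth away, too short to be a flank
        p = profile(
            [seg("chr1", 55, 70, 1, 1), seg("chr1", 70, 78, 2, 1),
             seg("chr1", 78, 100, 1, 1)]
        )
        assert count_lst(p, toy_annotation)[0] == 0

    def test_single_segment_genome(self, toy_annotation):
        p = profile([seg("chr1", 0, 100, 1, 1)])
        assert count_lst(p, toy_annotation)[0] == 0

    def test_transition_across_smoothed_gap_counts_once(self, toy_annotation):
        p = profile(
            [seg("chr1", 55, 80, 1, 1), seg("chr1", 80, 82, 3, 0),
             seg("chr1", 82, 100, 2, 1)]
        )
        assert count_lst(p, toy_annotation)[0] == 1


class TestHrdLoh:
    def test_large_terminal_loh_counts(self, toy_annotation):
        p = profile([seg("chr2", 0, 20, 2, 0), seg("chr2", 20, 80, 1, 1)])
        assert count_hrd_loh(p, toy_annotation)[0] == 1

    def test_whole_chromosome_loh_is_excluded(self, toy_annotation):
        p = profile([seg("chr2", 0, 80, 1, 0)])
        assert count_hrd_loh(p, toy_annotation)[0] == 0

    def test_short_loh_not_counted(self, toy_annotation):
        p = profile([seg("chr2", 0, 12, 1, 0), seg("chr2", 12, 80, 1, 1)])
        assert count_hrd_loh(p, toy_annotation)[0] == 0

    def test_run_merges_across_copy_state_change(self, toy_annotation):
        p = profile(
            [seg("chr2", 0, 10, 2, 0), seg("chr2", 10, 20, 1, 0),
             seg("chr2", 20, 80, 1, 1)]
        )
        count, (event,) = count_hrd_loh(p, toy_annotation)
        assert count == 1
        assert (event.region_start, event.region_end) == (0, mb(20))
        assert event.breakpoints == frozenset({("chr2", mb(20))})

    def test_homozygous_deletion_breaks_but_does_not_extend_run(self, toy_annotation):
        # 10 Mb LOH | 2 Mb (0,0) | 10 Mb LOH: neither piece exceeds 15 Mb
        p = profile(
            [seg("chr2", 0, 10, 1, 0), seg("chr2", 10, 12, 0, 0),
             seg("chr2", 12, 22, 1, 0), seg("chr2", 22, 80, 1, 1)]
        )
        assert count_hrd_loh(p, toy_annotation)[0] == 0

    def test_chromosome_exclusion_is_monotone(self, toy_annotation):
        p = profile(
            [seg("chr1", 0, 30, 1, 0), seg("chr1", 30, 100, 1, 1),
             seg("chr2", 0, 20, 2, 0), seg("chr2", 20, 80, 1, 1)]
        )
        default = count_hrd_loh(p, toy_annotation)[0]
        excluded = count_hrd_loh(
            p, toy_annotation, ScarConfig(loh_exclude_chroms=frozenset({"chr1"}))
        )[0]
        assert default == 2
        assert excluded == 1
        assert excluded <= default


class TestScoreSample:
    def test_balanced_diploid_genome_scores_zero(self, toy_annotation):
        p = profile(
            [seg("chr1", 0, 100, 1, 1), seg("chr2", 0, 80, 1, 1),
             seg("chr3", 0, 100, 1, 1)]
        )
        scores, events = score_sample(p, toy_annotation)
        assert (scores.ntai, scores.lst, scores.hrd_loh) == (0, 0, 0)
        assert events == []

    def test_one_event_per_signature(self, toy_annotation):
        # chr1: telomeric AI; chr2: interstitial 22 Mb LOH with sub-10 Mb
        # flanks (so it is not also an LST); chr3: balanced state transition
        p = profile(
            [seg("chr1", 0, 60, 1, 1), seg("chr1", 60, 100, 2, 1),
             seg("chr2", 0, 49, 1, 1), seg("chr2", 49, 71, 1, 0),
             seg("chr2", 71, 80, 1, 1),
             seg("chr3", 0, 80, 1, 1), seg("chr3", 80, 100, 2, 2)]
        )
        scores, events = score_sample(p, toy_annotation)
        assert (scores.ntai, scores.lst, scores.hrd_loh) == (1, 1, 1)
        assert len(events) == 3

    def test_scores_equal_event_counts(self, toy_annotation):
        p = profile(
            [seg("chr1", 0, 60, 1, 1), seg("chr1", 60, 100, 2, 1),
             seg("chr2", 0, 20, 2, 0), seg("chr2", 20, 80, 1, 1)]
        )
        scores, events = score_sample(p, toy_annotation)
        by_sig = {}
        for e in events:
            by_sig[e.signature] = by_sig.get(e.signature, 0) + 1
        assert scores.ntai == by_sig.get("NTAI", 0)
        assert scores.lst == by_sig.get("LST", 0)
        assert scores.hrd_loh == by_sig.get("HRD_LOH", 0)

    def test_sex_chromosomes_ignored_by_default(self):
        ann = GenomeAnnotation(
            (
                Chromosome("chr1", mb(100), mb(45), mb(55)),
                Chromosome("chrX", mb(100), mb(45), mb(55)),
            )
        )
        p = profile(
            [seg("chr1", 0, 100, 1, 1),
             seg("chrX", 0, 60, 1, 1), seg("chrX", 60, 100, 1, 0)]
        )
        scores, _ = score_sample(p, ann)
        assert (scores.ntai, scores.lst, scores.hrd_loh) == (0, 0, 0)
        with_sex, _ = score_sample(
            p, ann, ScarConfig(include_sex_chromosomes=True)
        )
        assert with_sex.ntai == 1


def _random_split(rng, segments):
    """Split one random segment into two abutting equal-state pieces."""
    segs = list(segments)
    candidates = [i for i, s in enumerate(segs) if s.length >= 2]
    i = rng.choice(candidates)
    s = segs[i]
    cut = rng.randrange(s.start + 1, s.end)
    segs[i:i + 1] = [
        Segment(s.chrom, s.start, cut, s.n_major, s.n_minor),
        Segment(s.chrom, cut, s.end, s.n_major, s.n_minor),
    ]
    return segs


class TestProperties:
    def test_scores_invariant_to_equal_state_splitting(self, toy_annotation):
        rng = random.Random(42)
        p = profile(
            [seg("chr1", 0, 60, 1, 1), seg("chr1", 60, 100, 2, 1),
             seg("chr2", 0, 20, 2, 0), seg("chr2", 20, 80, 1, 1),
             seg("chr3", 0, 80, 1, 1), seg("chr3", 80, 100, 2, 2)]
        )
        base, _ = score_sample(p, toy_annotation)
        segs = p.segments
        for _ in range(25):
            segs = _random_split(rng, segs)
            split_profile = profile(segs)
            split_scores, _ = score_sample(split_profile, toy_annotation)
            assert split_scores == base

    def test_chromosome_processing_order_is_irrelevant(self, toy_annotation):
        p = profile(
            [seg("chr1", 0, 60, 1, 1), seg("chr1", 60, 100, 2, 1),
             seg("chr2", 0, 20, 2, 0), seg("chr2", 20, 80, 1, 1)]
        )
        reversed_profile = profile(tuple(reversed(p.segments)))
        assert score_sample(p, toy_annotation)[0] == score_sample(
            reversed_profile, toy_annotation
        )[0]


# -- oracle equivalence -------------------------------------------------------

_STATES = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2), (3, 1), (3, 2)]


def _random_profile(rng, annotation):
    segments = []
    chroms = rng.sample(
        list(annotation.names), rng.randint(1, len(annotation.names))
    )
    budget = 20
    for chrom in chroms:
        length = annotation[chrom].length
        pos = rng.randrange(0, mb(10))
        while pos < length - mb(1) and budget > 0:
            size = rng.randrange(mb(1), mb(60))
            end = min(pos + size, length)
            segments.append(Segment(chrom, pos, end, *rng.choice(_STATES)))
            budget -= 1
            pos = end
            if rng.random() < 0.25:  # uncovered gap
                pos += rng.randrange(mb(1), mb(10))
    if not segments:
        segments.append(Segment(chroms[0], 0, mb(50), 1, 1))
    return profile(segments, sample_id="rand")


@pytest.fixture(scope="module")
def oracle_annotation():
    return GenomeAnnotation(
        (
            Chromosome("chr1", mb(240), mb(115), mb(125)),
            Chromosome("chr2", mb(190), mb(90), mb(97)),
            Chromosome("chr3", mb(150), mb(60), mb(68)),
            Chromosome("chr4", mb(100), mb(45), mb(55)),
            Chromosome("chr5", mb(60), mb(25), mb(30)),
        )
    )


class TestOracleEquivalence:
    def test_counters_agree_with_bruteforce_on_random_profiles(
        self, oracle_annotation
    ):
        rng = random.Random(20240501)
        for _ in range(1000):
            p = _random_profile(rng, oracle_annotation)
            for chrom in p.chromosomes():
                assert major_copy_state(p, chrom) == ref_major_state(p, chrom)
            assert count_ntai(p, oracle_annotation)[0] == ref_ntai(
                p, oracle_annotation
            )
            assert count_lst(p, oracle_annotation)[0] == ref_lst(
                p, oracle_annotation
            )
            assert count_hrd_loh(p, oracle_annotation)[0] == ref_hrd_loh(
                p, oracle_annotation
            )
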
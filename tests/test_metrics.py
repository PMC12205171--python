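"""Aligned read/base metrics: examples, conservation, oracle equivalence."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_categories, make_instance
from maglens.bins import REPORT_TIERS, QualityTier
from maglens.io import AlignmentRecord, ReadSetStats
from maglens.metrics import (
    binning_aware_stats,
    binning_unaware_stats,
    filter_alignments,
    interval_union,
    summarize_reads,
)


def rec(name, length, qs, qe, target, secondary=False):
    return AlignmentRecord(
        query_name=name, query_length=length, query_start=qs, query_end=qe,
        strand="+", target_name=target, target_length=10000,
        target_start=0, target_end=qe - qs, residue_matches=qe - qs,
        block_length=qe - qs, mapq=60, is_secondary=secondary,
    )


def stats_for(lengths: dict[str, int]) -> ReadSetStats:
    return ReadSetStats(len(lengths), sum(lengths.values()), dict(lengths))


class TestFilterAlignments:
    def test_default_keeps_everything(self):
        records = [rec("r", 1000, 0, s, "c") for s in (100, 500, 1000)]
        assert list(filter_alignments(records)) == records

    def test_threshold_is_inclusive_on_query_span(self):
        records = [rec("r", 1000, 0, s, "c") for s in (100, 500, 1000)]
        kept = list(filter_alignments(records, min_length=500))
        assert [r.query_span for r in kept] == [500, 1000]
        assert list(filter_alignments(records, min_length=501))[0].query_span == 1000

    def test_secondary_dropped_when_requested(self):
        records = [rec("r", 1000, 0, 500, "c", secondary=True),
                   rec("r", 1000, 0, 500, "c")]
        assert len(list(filter_alignments(records, count_secondary=False))) == 1


class TestIntervalUnion:
    @pytest.mark.parametrize(
        "intervals, merged, total",
        [
            ([], [], 0),
            ([(0, 60), (40, 100)], [(0, 100)], 100),
            ([(0, 10), (20, 30)], [(0, 10), (20, 30)], 20),
            ([(0, 10), (10, 20)], [(0, 20)], 20),  # touching coalesce
        ],
    )
    def test_examples(self, intervals, merged, total):
        assert interval_union(intervals) == (merged, total)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_union([(5, 5)])

    @given(
        st.lists(
            st.tuples(st.integers(0, 200), st.integers(1, 50)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=12,
        )
    )
    def test_matches_per_base_brute_force(self, intervals):
        merged, total = interval_union(intervals)
        covered = set()
        for s, e in intervals:
            covered.update(range(s, e))
        assert total == len(covered)
        from_merged = set()
        for s, e in merged:
            assert s < e
            assert not (from_merged & set(range(s, e)))  # disjoint
            from_merged.update(range(s, e))
        assert from_merged == covered
        assert merged == sorted(merged)


class TestSummarizeReads:
    tiers = {"cH": QualityTier.HIGH, "cL": QualityTier.LOW}

    def test_best_tier_wins_across_contigs(self):
        s = stats_for({"r1": 100})
        (summary,) = summarize_reads(
            [rec("r1", 100, 0, 50, "cH"), rec("r1", 100, 50, 100, "cL")],
            s, self.tiers,
        )
        assert summary.best_tier == QualityTier.HIGH

    def test_unaligned_read_gets_empty_buckets(self):
        (summary,) = summarize_reads([], stats_for({"r1": 100}), self.tiers)
        assert summary.best_tier == QualityTier.UNALIGNED
        assert summary.per_tier_intervals == {}

    def test_overlapping_same_tier_intervals_merge(self):
        s = stats_for({"r1": 100})
        (summary,) = summarize_reads(
            [rec("r1", 100, 0, 60, "cH"), rec("r1", 100, 40, 100, "cH")],
            s, self.tiers,
        )
        assert summary.per_tier_intervals[QualityTier.HIGH] == [(0, 100)]

    def test_unknown_read_rejected(self):
        with pytest.raises(KeyError, match="rX"):
            summarize_reads([rec("rX", 100, 0, 50, "cH")],
                            stats_for({"r1": 100}), self.tiers)


class TestBinningUnaware:
    def test_no_read_aligned(self):
        s = stats_for({"r1": 100, "r2": 50})
        summaries = summarize_reads([], s, {})
        assert binning_unaware_stats(summaries, s) == (0.0, 0.0)

    def test_everything_covered(self):
        s = stats_for({"r1": 100, "r2": 50})
        records = [rec("r1", 100, 0, 100, "c"), rec("r2", 50, 0, 50, "c")]
        summaries = summarize_reads(records, s, {"c": QualityTier.UNBINNED})
        assert binning_unaware_stats(summaries, s) == (100.0, 100.0)

    def test_three_of_four_reads(self):
        s = stats_for({f"r{i}": 100 for i in range(4)})
        records = [rec(f"r{i}", 100, 0, 100, "c") for i in range(3)]
        summaries = summarize_reads(records, s, {"c": QualityTier.UNBINNED})
        assert binning_unaware_stats(summaries, s) == (75.0, 75.0)

    def test_empty_read_set_rejected(self):
        s = stats_for({})
        with pytest.raises(ValueError):
            binning_unaware_stats([], s)


class TestBinningAware:
    def test_four_tier_symmetry(self):
        s = stats_for({f"r{i}": 100 for i in range(4)})
        tiers = [QualityTier.NEAR_COMPLETE, QualityTier.HIGH,
                 QualityTier.MEDIUM, QualityTier.LOW]
        records = [rec(f"r{i}", 100, 0, 100, f"c{i}") for i in range(4)]
        lookup = {f"c{i}": t for i, t in enumerate(tiers)}
        report = binning_aware_stats(summarize_reads(records, s, lookup), s)
        for t in tiers:
            assert report.categories[t].read_percent == 25.0
            assert report.categories[t].base_percent == 25.0

    def test_base_attribution_best_tier_per_base(self):
        """Overlap between tiers: each base goes to the best covering tier."""
        s = stats_for({"r1": 100})
        records = [rec("r1", 100, 0, 50, "cH"), rec("r1", 100, 25, 100, "cU")]
        lookup = {"cH": QualityTier.HIGH, "cU": QualityTier.UNBINNED}
        report = binning_aware_stats(summarize_reads(records, s, lookup), s)
        assert report.categories[QualityTier.HIGH].base_count == 50
        assert report.categories[QualityTier.UNBINNED].base_count == 50
        assert report.categories[QualityTier.UNALIGNED].base_count == 0
        assert report.categories[QualityTier.HIGH].read_count == 1

    def test_fully_unaligned_read(self):
        s = stats_for({"r1": 100})
        report = binning_aware_stats(summarize_reads([], s, {}), s)
        assert report.categories[QualityTier.UNALIGNED].read_percent == 100.0
        assert report.categories[QualityTier.UNALIGNED].base_percent == 100.0

    def test_partial_read_tail_is_unaligned(self):
        s = stats_for({"r1": 100})
        records = [rec("r1", 100, 10, 60, "cH")]
        report = binning_aware_stats(
            summarize_reads(records, s, {"cH": QualityTier.HIGH}), s
        )
        assert report.categories[QualityTier.HIGH].base_count == 50
        assert report.categories[QualityTier.UNALIGNED].base_count == 50


def run_engine(inst, min_length=0, count_secondary=True):
    retained = filter_alignments(inst.records, min_length, count_secondary)
    summaries = summarize_reads(retained, inst.read_stats, inst.tier_of_contig)
    return binning_aware_stats(summaries, inst.read_stats, min_length)


class TestOracleEquivalence:
    def test_random_instances_match_per_base_oracle(self):
        rng = random.Random(4215)
        for trial in range(200):
            inst = make_instance(rng)
            min_length = rng.choice([0, 0, 10, 50])
            secondary = rng.random() < 0.7
            report = run_engine(inst, min_length, secondary)
            expected = brute_force_categories(inst, min_length, secondary)
            for tier in REPORT_TIERS:
                c = report.categories[tier]
                assert c.read_count == expected[tier]["read_count"], (trial, tier)
                assert c.base_count == expected[tier]["base_count"], (trial, tier)

    def test_conservation(self):
        rng = random.Random(977)
        for _ in range(50):
            inst = make_instance(rng)
            report = run_engine(inst)
            report.validate()  # raises if counts/percentages do not conserve

    def test_threshold_monotonicity(self):
        rng = random.Random(515)
        for _ in range(25):
            inst = make_instance(rng)
            prev_read, prev_base = 100.0, 100.0
            for min_length in (0, 5, 20, 50, 100, 200):
                summaries = summarize_reads(
                    filter_alignments(inst.records, min_length),
                    inst.read_stats, inst.tier_of_contig,
                )
                r, b = binning_unaware_stats(summaries, inst.read_stats)
                assert r <= prev_read + 1e-12
                assert b <= prev_base + 1e-12
                prev_read, prev_base = r, b

    def test_all_unbinned_collapses_to_unaware(self):
        rng = random.Random(31)
        for _ in range(25):
            inst = make_instance(rng)
            inst.tier_of_contig = {
                c: QualityTier.UNBINNED for c in inst.tier_of_contig
            }
            summaries = summarize_reads(
                inst.records, inst.read_stats, inst.tier_of_contig
            )
            r, b = binning_unaware_stats(summaries, inst.read_stats)
            report = binning_aware_stats(summaries, inst.read_stats)
            assert report.categories[QualityTier.UNBINNED].read_percent == pytest.approx(r)
            assert report.categories[QualityTier.UNBINNED].base_percent == pytest.approx(b)
            assert report.categories[QualityTier.UNALIGNED].read_percent == pytest.approx(100 - r)
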
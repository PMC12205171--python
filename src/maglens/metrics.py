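"""Aligned read/base percentage metrics, binning-unaware and binning-aware.

The two core statistics of the evaluation engine:

* **aligned read percentage** — reads with at least one retained alignment
  to a contig, over the total number of reads;
* **aligned base percentage** — read bases covered by at least one retained
  alignment (interval union per read, so overlapping placements are not
  double-counted), over the total read length.

With binning information each percentage is split by the quality tier of
the contigs' bins. A read aligned to several contigs counts only toward the
best tier it reaches; a base covered by several alignments is attributed to
the best tier of any alignment covering it, so reads and bases each sum
exactly to the totals (the stacked 100% bars of the summary plot).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .bins import REPORT_TIERS, QualityTier
from .io import AlignmentRecord, ReadSetStats

__all__ = [
    "ReadAlignmentSummary",
    "CategoryStats",
    "AlignedStatsReport",
    "filter_alignments",
    "interval_union",
    "summarize_reads",
    "binning_unaware_stats",
    "binning_aware_stats",
]


@dataclass(slots=True)
class ReadAlignmentSummary:
    """Per-read attribution state.

    ``per_tier_intervals`` holds, for each tier with at least one retained
    alignment, the merged disjoint sorted query intervals covered at that
    tier. ``best_tier`` is the maximum such tier, or UNALIGNED when the read
    has no retained alignment.
    """

    read_name: str
    read_length: int
    best_tier: QualityTier
    per_tier_intervals: dict[QualityTier, list[tuple[int, int]]] = field(
        default_factory=dict
    )


@dataclass(slots=True)
class CategoryStats:
    """Counts and percentages for one report category."""

    read_count: int = 0
    base_count: int = 0
    read_percent: float = 0.0
    base_percent: float = 0.0


@dataclass(slots=True)
class AlignedStatsReport:
    """The full binning-aware report (one row per category, best first)."""

    categories: dict[QualityTier, CategoryStats]
    total_reads: int
    total_bases: int
    min_alignment_length: int

    def validate(self) -> None:
        """Check the conservation invariants (exact on counts)."""
        if sum(c.read_count for c in self.categories.values()) != self.total_reads:
            raise AssertionError("category read counts do not sum to total reads")
        if sum(c.base_count for c in self.categories.values()) != self.total_bases:
            raise AssertionError("category base counts do not sum to total bases")
        for name, total in (("read_percent", 100.0), ("base_percent", 100.0)):
            s = sum(getattr(c, name) for c in self.categories.values())
            if abs(s - total) > 1e-9:
                raise AssertionError(f"{name} sums to {s}, expected 100")


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_length: int = 0,
    count_secondary: bool = True,
    use_block_length: bool = False,
) -> Iterator[AlignmentRecord]:
    """Retain alignments meeting the length threshold.

    The default ``min_length=0`` with secondary alignments kept reproduces
    the all-alignments behaviour. Length is the query span (read bases
    covered) by default — indel-robust — or the PAF block length when
    ``use_block_length`` is set. The threshold is inclusive (>=).
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    for rec in records:
        if not count_secondary and rec.is_secondary:
            continue
        length = rec.block_length if use_block_length else rec.query_span
        if length >= min_length:
            yield rec


def interval_union(
    intervals: Iterable[tuple[int, int]],
) -> tuple[list[tuple[int, int]], int]:
    """Merge half-open intervals into a disjoint sorted list.

    Returns the merged list and the total covered length. Touching
    intervals coalesce. Empty input gives ``([], 0)``.
    """
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"degenerate interval [{start}, {end})")
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged, sum(e - s for s, e in merged)


def summarize_reads(
    records: Iterable[AlignmentRecord],
    read_stats: ReadSetStats,
    tier_lookup: Mapping[str, QualityTier],
) -> list[ReadAlignmentSummary]:
    """Group retained alignments by read and attribute intervals to tiers.

    Every read of the read set yields a summary; reads with no retained
    alignment come out with ``best_tier = UNALIGNED`` and empty buckets.
    An alignment naming a read absent from the read set is an error (the
    alignment file and the FASTQ are out of sync).
    """
    buckets: dict[str, dict[QualityTier, list[tuple[int, int]]]] = {}
    for rec in records:
        if rec.query_name not in read_stats.lengths:
            raise KeyError(
                f"alignment query {rec.query_name!r} not present in the read set"
            )
        tier = tier_lookup[rec.target_name]
        buckets.setdefault(rec.query_name, {}).setdefault(tier, []).append(
            (rec.query_start, rec.query_end)
        )

    summaries: list[ReadAlignmentSummary] = []
    for name, length in read_stats.lengths.items():
        per_tier = buckets.get(name)
        if not per_tier:
            summaries.append(
                ReadAlignmentSummary(name, length, QualityTier.UNALIGNED)
            )
            continue
        merged = {
            tier: interval_union(ivals)[0] for tier, ivals in per_tier.items()
        }
        summaries.append(
            ReadAlignmentSummary(name, length, max(merged), merged)
        )
    return summaries


def binning_unaware_stats(
    summaries: Iterable[ReadAlignmentSummary],
    read_stats: ReadSetStats,
) -> tuple[float, float]:
    """The two headline percentages, ignoring binning.

    Returns ``(aligned_read_percent, aligned_base_percent)``. The base
    numerator is the per-read union of query intervals across all tiers, so
    a base never counts twice however many alignments cover it.
    """
    if read_stats.read_count == 0:
        raise ValueError("aligned percentages undefined for an empty read set")
    aligned_reads = 0
    aligned_bases = 0
    for s in summaries:
        if s.best_tier != QualityTier.UNALIGNED:
            aligned_reads += 1
            all_ivals = [iv for ivals in s.per_tier_intervals.values() for iv in ivals]
            aligned_bases += interval_union(all_ivals)[1]
    return (
        100.0 * aligned_reads / read_stats.read_count,
        100.0 * aligned_bases / read_stats.total_bases,
    )


def binning_aware_stats(
    summaries: Iterable[ReadAlignmentSummary],
    read_stats: ReadSetStats,
    min_alignment_length: int = 0,
) -> AlignedStatsReport:
    """Split the aligned read/base percentages by bin quality tier.

    Each read is counted once, in its best tier. Each base is attributed to
    the best tier among the alignments covering it: tiers are processed
    best-first and each tier receives only the bases not already claimed by
    a better tier. Bases of a partially aligned read outside every
    alignment, like whole unaligned reads, land in UNALIGNED. Read and base
    counts therefore both sum exactly to the read-set totals.
    """
    if read_stats.read_count == 0:
        raise ValueError("aligned percentages undefined for an empty read set")
    cats = {tier: CategoryStats() for tier in REPORT_TIERS}

    for s in summaries:
        cats[s.best_tier].read_count += 1
        claimed: list[tuple[int, int]] = []
        claimed_len = 0
        for tier in REPORT_TIERS[:-1]:  # best first, contig tiers only
            ivals = s.per_tier_intervals.get(tier)
            if not ivals:
                continue
            merged, total = interval_union(claimed + ivals)
            cats[tier].base_count += total - claimed_len
            claimed, claimed_len = merged, total
        cats[QualityTier.UNALIGNED].base_count += s.read_length - claimed_len

    for c in cats.values():
        c.read_percent = 100.0 * c.read_count / read_stats.read_count
        c.base_percent = (
            100.0 * c.base_count / read_stats.total_bases
            if read_stats.total_bases
            else 0.0
        )

    report = AlignedStatsReport(
        categories=cats,
        total_reads=read_stats.read_count,
        total_bases=read_stats.total_bases,
        min_alignment_length=min_alignment_length,
    )
    report.validate()
    return report
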
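"""End-to-end wiring: files in, report out.

Thin composition layer over the format readers and the metric engine, used
by both the command-line interface and the test harness.
"""

from __future__ import annotations

from pathlib import Path

from . import io as mio
from .bins import CONTIG_TIERS, QualityTier, classify_bins
from .metrics import (
    AlignedStatsReport,
    ReadAlignmentSummary,
    binning_aware_stats,
    filter_alignments,
    summarize_reads,
)

__all__ = ["build_tier_lookup", "compute_report"]


def build_tier_lookup(
    bins_source: str | Path | None,
    quality_path: str | Path | None,
    contig_names: set[str],
) -> dict[str, QualityTier]:
    """Per-contig tier lookup covering ``contig_names``.

    Without binning inputs every contig is UNBINNED, which collapses the
    binning-aware report onto the binning-unaware one (UNBINNED = aligned).
    """
    if bins_source is None:
        return {c: QualityTier.UNBINNED for c in contig_names}
    bin_map = mio.read_bin_map(bins_source)
    if quality_path is None:
        raise ValueError("binning given without a quality table")
    qualities = mio.read_quality_table(quality_path, bin_map.contig_counts())
    tiers = classify_bins(qualities)
    lookup: dict[str, QualityTier] = {}
    for contig in contig_names:
        bin_name = bin_map.bin_of(contig)
        if bin_name is None:
            lookup[contig] = QualityTier.UNBINNED
        elif bin_name in tiers:
            lookup[contig] = tiers[bin_name]
        else:
            raise KeyError(f"bin {bin_name!r} has no quality record")
    return lookup


def compute_report(
    paf_path: str | Path,
    reads_path: str | Path,
    bins_source: str | Path | None = None,
    quality_path: str | Path | None = None,
    min_alignment_length: int = 0,
    count_secondary: bool = True,
    use_block_length: bool = False,
) -> tuple[AlignedStatsReport, list[ReadAlignmentSummary], mio.ReadSetStats]:
    """Full metric run on files: returns (report, summaries, read stats)."""
    read_stats = mio.scan_reads(reads_path)
    records = list(
        filter_alignments(
            mio.read_paf(paf_path),
            min_length=min_alignment_length,
            count_secondary=count_secondary,
            use_block_length=use_block_length,
        )
    )
    contig_names = {r.target_name for r in records}
    tier_lookup = build_tier_lookup(bins_source, quality_path, contig_names)
    summaries = summarize_reads(records, read_stats, tier_lookup)
    report = binning_aware_stats(summaries, read_stats, min_alignment_length)
    return report, summaries, read_stats
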
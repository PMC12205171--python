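"""MAG quality-tier classification.

Bins are placed into four ordered quality tiers from their CheckM2-style
completeness and contamination estimates, following the thresholds commonly
used for metagenome-assembled genomes:

* near complete — single contig, completeness >= 99%, contamination <= 1%
* high quality  — completeness >= 90%, contamination <= 5%
* medium quality — completeness >= 50%, contamination <= 10%
* low quality   — everything else

All threshold comparisons are inclusive. Two extra categories exist for
report accounting: UNBINNED for assembled contigs outside any bin, and
UNALIGNED for reads with no retained alignment (never used for contigs).
"""

from __future__ import annotations

import enum
from typing import Mapping

from .io import BinQuality, ContigBinMap

__all__ = ["QualityTier", "classify_tier", "classify_bins", "tier_of_contig"]


class QualityTier(enum.IntEnum):
    """Ordered category; higher value = better tier.

    LOW ranks above UNBINNED: a contig in even a poor bin carries more
    binning signal than one in no bin at all.
    """

    UNALIGNED = 0
    UNBINNED = 1
    LOW = 2
    MEDIUM = 3
    HIGH = 4
    NEAR_COMPLETE = 5

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    QualityTier.NEAR_COMPLETE: "near complete",
    QualityTier.HIGH: "high quality",
    QualityTier.MEDIUM: "medium quality",
    QualityTier.LOW: "low quality",
    QualityTier.UNBINNED: "unbinned",
    QualityTier.UNALIGNED: "unaligned",
}

#: Tiers a contig can hold (reads additionally admit UNALIGNED).
CONTIG_TIERS = (
    QualityTier.NEAR_COMPLETE,
    QualityTier.HIGH,
    QualityTier.MEDIUM,
    QualityTier.LOW,
    QualityTier.UNBINNED,
)

#: All report categories, best first.
REPORT_TIERS = CONTIG_TIERS + (QualityTier.UNALIGNED,)


def classify_tier(q: BinQuality) -> QualityTier:
    """Classify one bin into its quality tier.

    Rules are evaluated best-first and the first match wins; because the
    predicate sets are nested in completeness and contamination this equals
    picking the best satisfied tier. The single-contig gate applies only to
    the near-complete tier.
    """
    if q.contig_count == 1 and q.completeness >= 99 and q.contamination <= 1:
        return QualityTier.NEAR_COMPLETE
    if q.completeness >= 90 and q.contamination <= 5:
        return QualityTier.HIGH
    if q.completeness >= 50 and q.contamination <= 10:
        return QualityTier.MEDIUM
    return QualityTier.LOW


def classify_bins(qualities: list[BinQuality]) -> dict[str, QualityTier]:
    """Tier lookup keyed by bin name."""
    return {q.bin_name: classify_tier(q) for q in qualities}


def tier_of_contig(
    contig_name: str,
    bin_map: ContigBinMap,
    tiers: Mapping[str, QualityTier],
) -> QualityTier:
    """Tier of the bin holding ``contig_name``, or UNBINNED if in no bin.

    Raises
    ------
    KeyError
        If the contig's bin has no quality record — the bin map and the
        quality table are out of sync.
    """
    bin_name = bin_map.bin_of(contig_name)
    if bin_name is None:
        return QualityTier.UNBINNED
    try:
        return tiers[bin_name]
    except KeyError:
        raise KeyError(
            f"bin {bin_name!r} (holding contig {contig_name!r}) has no "
            "quality record"
        ) from None
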
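"""Text reports, machine-readable TSVs and the stacked summary plot."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .bins import REPORT_TIERS, QualityTier
from .metrics import AlignedStatsReport

__all__ = [
    "largest_remainder_round",
    "render_text_report",
    "write_report_tsv",
    "render_stacked_plot",
]

#: Fixed category colour map (best tier first); ordering is never configurable
#: so reports from different runs stay comparable.
DEFAULT_COLORS = {
    QualityTier.NEAR_COMPLETE: "#1b7837",
    QualityTier.HIGH: "#7fbf7b",
    QualityTier.MEDIUM: "#d9f0d3",
    QualityTier.LOW: "#e7d4e8",
    QualityTier.UNBINNED: "#af8dc3",
    QualityTier.UNALIGNED: "#762a83",
}


def largest_remainder_round(values: Sequence[float], decimals: int = 1) -> list[float]:
    """Round percentages so the rounded values sum exactly to the true sum.

    Standard largest-remainder apportionment at the given decimal
    resolution: floor everything, then hand out the remaining units to the
    entries with the largest fractional parts (ties by position).
    """
    scale = 10**decimals
    scaled = [v * scale for v in values]
    floors = [int(x) for x in scaled]
    target = int(round(sum(scaled)))
    remainder = target - sum(floors)
    by_frac = sorted(
        range(len(values)), key=lambda i: (-(scaled[i] - floors[i]), i)
    )
    out = list(floors)
    for i in by_frac[:remainder]:
        out[i] += 1
    return [x / scale for x in out]


def _display_percents(report: AlignedStatsReport, tiers: Sequence[QualityTier]):
    reads = largest_remainder_round(
        [report.categories[t].read_percent for t in tiers]
    )
    bases = largest_remainder_round(
        [report.categories[t].base_percent for t in tiers]
    )
    return reads, bases


def render_text_report(report: AlignedStatsReport, mode: str = "binning_aware") -> str:
    """Fixed-layout text report.

    ``binning_aware`` prints one row per quality tier; ``binning_unaware``
    collapses the contig tiers into a single aligned row. Percentages are
    shown to one decimal, reconciled so each column sums to 100.0; full
    precision lives in the TSV output.
    """
    lines = [
        f"alignment length threshold: {report.min_alignment_length}",
        f"total reads: {report.total_reads}",
        f"total bases: {report.total_bases}",
        "",
        f"{'category':<16}{'reads':>12}{'reads%':>8}{'bases':>14}{'bases%':>8}",
    ]
    if mode == "binning_aware":
        tiers = list(REPORT_TIERS)
        reads_pct, bases_pct = _display_percents(report, tiers)
        for tier, rp, bp in zip(tiers, reads_pct, bases_pct):
            c = report.categories[tier]
            lines.append(
                f"{tier.label:<16}{c.read_count:>12}{rp:>8.1f}"
                f"{c.base_count:>14}{bp:>8.1f}"
            )
    elif mode == "binning_unaware":
        un = report.categories[QualityTier.UNALIGNED]
        aligned_reads = report.total_reads - un.read_count
        aligned_bases = report.total_bases - un.base_count
        rp = largest_remainder_round(
            [100.0 * aligned_reads / report.total_reads, un.read_percent]
        )
        bp = largest_remainder_round(
            [100.0 * aligned_bases / report.total_bases, un.base_percent]
        )
        lines.append(
            f"{'aligned':<16}{aligned_reads:>12}{rp[0]:>8.1f}"
            f"{aligned_bases:>14}{bp[0]:>8.1f}"
        )
        lines.append(
            f"{'unaligned':<16}{un.read_count:>12}{rp[1]:>8.1f}"
            f"{un.base_count:>14}{bp[1]:>8.1f}"
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return "\n".join(lines) + "\n"


def write_report_tsv(
    report: AlignedStatsReport, path: str | Path, provenance: Sequence[str] = ()
) -> None:
    """Machine-readable report: full-precision percentages, one tier per row."""
    with open(path, "wt") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        fh.write("category\tread_count\tbase_count\tread_percent\tbase_percent\n")
        for tier in REPORT_TIERS:
            c = report.categories[tier]
            fh.write(
                f"{tier.label}\t{c.read_count}\t{c.base_count}\t"
                f"{c.read_percent!r}\t{c.base_percent!r}\n"
            )


def render_stacked_plot(
    report: AlignedStatsReport, title: str, out: str | Path
) -> None:
    """Two stacked 100% bars (reads, bases), one segment per category.

    Writes the image in the format implied by the extension (PNG/SVG) plus
    a ``<out>.tsv`` sidecar of the plotted percentages, so figures are
    testable without image comparison.
    """
    out = Path(out)
    tiers = list(REPORT_TIERS)
    read_pcts = [report.categories[t].read_percent for t in tiers]
    base_pcts = [report.categories[t].base_percent for t in tiers]

    fig, ax = plt.subplots(figsize=(4.5, 5.5))
    bottoms = [0.0, 0.0]
    for tier, rp, bp in zip(tiers, read_pcts, base_pcts):
        ax.bar(
            ["reads", "bases"],
            [rp, bp],
            bottom=list(bottoms),
            label=tier.label,
            color=DEFAULT_COLORS[tier],
            edgecolor="black",
            linewidth=0.4,
        )
        bottoms[0] += rp
        bottoms[1] += bp
    ax.set_ylabel("percent of read set")
    ax.set_ylim(0, 100)
    ax.set_title(title)
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)

    with open(f"{out}.tsv", "wt") as fh:
        fh.write("category\tread_percent\tbase_percent\n")
        for tier, rp, bp in zip(tiers, read_pcts, base_pcts):
            fh.write(f"{tier.label}\t{rp!r}\t{bp!r}\n")
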
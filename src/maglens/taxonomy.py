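"""Compare taxonomic profiles of two read sets from Kraken-style reports.

Two questions drive the comparison of aligned ("assembled") versus
unaligned reads:

1. *Resolution* — within a clade (say Bacteria), what fraction of its reads
   is classified down to a given rank (say phylum) or deeper? Unassembled
   reads are typically resolved less precisely, indicating populations
   poorly represented in the reference database.
2. *Exclusivity* — which clades are detected in only one of the two sets?
   Clades seen only among unaligned reads were missed by the assembly.

The module consumes pre-computed Kraken2 report files; it never runs a
classifier.
"""

from __future__ import annotations

from typing import Sequence

from .io import KrakenReportRow

__all__ = ["rank_order", "rank_resolution", "exclusive_clades", "subtree_rows"]

#: Canonical rank ladder, root-most first. Suffixed codes (P1, G2, ...)
#: inherit their base letter's position.
_RANK_ORDER = "RDKPCOFGS"


def rank_order(rank_code: str) -> int | None:
    """Position of a rank code on the canonical ladder; None if unranked.

    Unclassified ('U') and no-rank ('-') rows have no position: they can
    belong to a subtree but never satisfy a target rank themselves.
    """
    if not rank_code:
        return None
    base = rank_code[0].upper()
    if base in _RANK_ORDER:
        return _RANK_ORDER.index(base)
    return None


def _find_clade(rows: Sequence[KrakenReportRow], clade_name: str) -> int:
    hits = [i for i, r in enumerate(rows) if r.name == clade_name]
    if not hits:
        raise ValueError(f"clade {clade_name!r} not found in report")
    if len(hits) > 1:
        raise ValueError(f"clade {clade_name!r} appears {len(hits)} times in report")
    return hits[0]


def subtree_rows(
    rows: Sequence[KrakenReportRow], clade_index: int
) -> list[KrakenReportRow]:
    """The clade row plus every row of its subtree (file order is DFS)."""
    root = rows[clade_index]
    out = [root]
    for row in rows[clade_index + 1 :]:
        if row.depth <= root.depth:
            break
        out.append(row)
    return out


def rank_resolution(
    rows: Sequence[KrakenReportRow],
    clade_name: str,
    target_rank: str,
    mode: str = "at_or_below",
) -> float:
    """Percentage of a clade's reads classified at ``target_rank`` or deeper.

    The numerator sums ``direct_reads`` over subtree rows whose rank code
    sits at the target rank or at a more specific one (``mode="exact"``
    restricts to exactly the target rank); the denominator is the clade's
    ``clade_reads``. No-rank rows never satisfy the target.
    """
    idx = _find_clade(rows, clade_name)
    clade = rows[idx]
    target = rank_order(target_rank)
    if target is None:
        raise ValueError(f"target rank {target_rank!r} is not a ranked code")
    clade_rank = rank_order(clade.rank_code)
    if clade_rank is not None and target <= clade_rank:
        raise ValueError(
            f"target rank {target_rank!r} is not below the clade's rank "
            f"{clade.rank_code!r}"
        )
    if clade.clade_reads == 0:
        raise ValueError(f"clade {clade_name!r} has no reads")
    num = 0
    for row in subtree_rows(rows, idx):
        r = rank_order(row.rank_code)
        if r is None:
            continue
        if (mode == "at_or_below" and r >= target) or (
            mode == "exact" and r == target
        ):
            num += row.direct_reads
    return 100.0 * num / clade.clade_reads


def exclusive_clades(
    rows_a: Sequence[KrakenReportRow],
    rows_b: Sequence[KrakenReportRow],
    rank: str,
    min_reads: int = 1,
) -> tuple[dict[str, int], dict[str, int]]:
    """Clades at ``rank`` detected in only one of two reports.

    A clade is *detected* when its ``clade_reads`` reaches ``min_reads``;
    the threshold is applied before the set difference, so a clade below
    threshold in both reports appears in neither output. Clades are matched
    by name at the requested rank (two reports produced by independent
    classifier runs need not agree on taxids).

    Returns ``(only_in_a, only_in_b)``, each mapping clade name to its
    ``clade_reads`` in the report where it was detected.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    target = rank_order(rank)
    if target is None:
        raise ValueError(f"rank {rank!r} is not a ranked code")

    def detected(rows: Sequence[KrakenReportRow]) -> dict[str, int]:
        return {
            row.name: row.clade_reads
            for row in rows
            if rank_order(row.rank_code) == target and row.clade_reads >= min_reads
        }

    da, db = detected(rows_a), detected(rows_b)
    only_a = {name: n for name, n in da.items() if name not in db}
    only_b = {name: n for name, n in db.items() if name not in da}
    return only_a, only_b
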
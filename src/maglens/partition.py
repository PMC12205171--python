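"""Partition a read set into aligned and unaligned subsets.

The unaligned ("unassembled") reads are the interesting ones: comparing
their k-mer abundance and taxonomic profile against the aligned reads shows
what the assembly missed. The partition uses the same retained-alignment
settings (length threshold, secondary handling) as the percentage metrics,
so "unaligned" means the same thing everywhere.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable

from .bins import QualityTier
from .io import iter_fastq
from .metrics import ReadAlignmentSummary

__all__ = ["partition_reads"]


def _open_out(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def partition_reads(
    reads_path: str | Path,
    summaries: Iterable[ReadAlignmentSummary],
    out_aligned: str | Path,
    out_unaligned: str | Path,
) -> tuple[int, int]:
    """Write aligned and unaligned reads to two FASTQ files.

    A read goes to the aligned file iff its summary's best tier is not
    UNALIGNED. Records are copied verbatim (name, sequence, quality) in
    input order. Output paths ending in ``.gz`` are gzip-compressed.

    Returns ``(aligned_count, unaligned_count)``.

    Raises
    ------
    KeyError
        If a read in the FASTQ has no summary (inputs out of sync).
    """
    is_aligned = {
        s.read_name: s.best_tier != QualityTier.UNALIGNED for s in summaries
    }
    n_aligned = 0
    n_unaligned = 0
    with _open_out(out_aligned) as fa, _open_out(out_unaligned) as fu:
        for name, seq, qual in iter_fastq(reads_path):
            try:
                aligned = is_aligned[name]
            except KeyError:
                raise KeyError(
                    f"read {name!r} has no alignment summary; the FASTQ and "
                    "the alignments are out of sync"
                ) from None
            record = f"@{name}\n{seq}\n+\n{qual}\n"
            if aligned:
                fa.write(record)
                n_aligned += 1
            else:
                fu.write(record)
                n_unaligned += 1
    return n_aligned, n_unaligned
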
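"""Per-read abundance from canonical k-mer counts.

A read's abundance in the sample is proxied by its *median k-mer
abundance*: count every canonical k-mer of the full read dataset, then take
the median count over each read's windows. Low-abundance reads (median 1)
carry sequence seen nowhere else — exactly the reads an assembler cannot
anchor, which is why the aligned/unaligned abundance histograms are
diagnostic of coverage-limited assemblies.

Counting is exact (plain hash table): the table for a HiFi dataset of
desk-test size fits trivially in memory; for multi-Gbp runs an external
counter can be substituted upstream, the median logic is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import iter_fastq

__all__ = [
    "KmerCountTable",
    "ReadAbundance",
    "canonical",
    "count_kmers",
    "median_abundance",
    "profile_reads",
    "abundance_histograms",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a window and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(slots=True)
class KmerCountTable:
    """Exact canonical k-mer counts over a read dataset."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    total_kmers: int = 0
    skipped_windows: int = 0  # windows containing non-ACGT characters

    def count_of(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)


@dataclass(frozen=True, slots=True)
class ReadAbundance:
    """Median k-mer abundance of one read; None when no window exists."""

    read_name: str
    median_abundance: int | None

    @property
    def defined(self) -> bool:
        return self.median_abundance is not None


def _windows(seq: str, k: int) -> Iterable[str]:
    """Unambiguous (ACGT-only) windows of length k, uppercased."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def count_kmers(paths: Sequence[str | Path] | str | Path, k: int) -> KmerCountTable:
    """Count canonical k-mers over one or more FASTQ files (the full dataset).

    Windows containing ambiguity codes (N etc.) are skipped and tallied in
    ``skipped_windows``. If no read reaches length k the table is empty —
    a warning condition, not an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(paths, (str, Path)):
        paths = [paths]
    table = KmerCountTable(k=k)
    counts = table.counts
    for path in paths:
        for _name, seq, _qual in iter_fastq(path):
            for window in _windows(seq, k):
                if set(window) <= _VALID:
                    key = canonical(window)
                    counts[key] = counts.get(key, 0) + 1
                    table.total_kmers += 1
                else:
                    table.skipped_windows += 1
    return table


def median_abundance(
    read_name: str,
    sequence: str,
    table: KmerCountTable,
    even_rule: str = "lower",
) -> ReadAbundance:
    """Median count, over the dataset, of a read's canonical windows.

    For an even number of windows the lower middle value is taken by
    default, keeping the statistic integral and conservative toward low
    abundance; ``even_rule="mean"`` averages the two middle values instead.
    Reads with no unambiguous window of length k get an undefined abundance
    (a value, not an error).
    """
    vals = sorted(
        table.count_of(w) for w in _windows(sequence, table.k) if set(w) <= _VALID
    )
    if not vals:
        return ReadAbundance(read_name, None)
    n = len(vals)
    if n % 2 == 1 or even_rule == "lower":
        med = vals[(n - 1) // 2]
    elif even_rule == "mean":
        med = (vals[n // 2 - 1] + vals[n // 2]) / 2
    else:
        raise ValueError(f"unknown even_rule {even_rule!r}")
    return ReadAbundance(read_name, med)


def profile_reads(
    path: str | Path, table: KmerCountTable, even_rule: str = "lower"
) -> list[ReadAbundance]:
    """Median abundance for every read of a FASTQ file."""
    return [
        median_abundance(name, seq, table, even_rule)
        for name, seq, _ in iter_fastq(path)
    ]


def abundance_histograms(
    aligned: Sequence[ReadAbundance],
    unaligned: Sequence[ReadAbundance],
    max_bin: int = 100,
    out_prefix: str | Path | None = None,
) -> dict:
    """Bin both abundance distributions on a shared integer axis.

    Bins are 1..max_bin plus one overflow bin; undefined abundances are
    excluded and their count reported. When ``out_prefix`` is given, writes
    ``<prefix>.hist.tsv`` (bin, aligned_count, unaligned_count) and an
    overlay figure ``<prefix>.hist.png``.

    Returns a dict with keys ``bins`` (labels), ``aligned``, ``unaligned``
    (counts per bin) and ``excluded`` (undefined per series).
    """
    if max_bin < 1:
        raise ValueError("max_bin must be >= 1")
    if not aligned and not unaligned:
        raise ValueError("both abundance lists are empty")

    def _bin(series: Sequence[ReadAbundance]) -> tuple[list[int], int]:
        counts = [0] * (max_bin + 1)  # index max_bin = overflow
        undefined = 0
        for ra in series:
            if ra.median_abundance is None:
                undefined += 1
                continue
            a = max(1, int(ra.median_abundance))  # abundance >= 1 when the
            # table covers the read's own dataset; clamp defensively
            counts[min(a, max_bin + 1) - 1] += 1
        return counts, undefined

    a_counts, a_undef = _bin(aligned)
    u_counts, u_undef = _bin(unaligned)
    labels = [str(i) for i in range(1, max_bin + 1)] + [f">{max_bin}"]
    result = {
        "bins": labels,
        "aligned": a_counts,
        "unaligned": u_counts,
        "excluded": {"aligned": a_undef, "unaligned": u_undef},
    }

    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        with open(f"{out_prefix}.hist.tsv", "wt") as fh:
            fh.write("bin\taligned_count\tunaligned_count\n")
            for lbl, ac, uc in zip(labels, a_counts, u_counts):
                fh.write(f"{lbl}\t{ac}\t{uc}\n")
        x = range(1, max_bin + 2)
        fig, ax = plt.subplots(figsize=(8, 4.5))
        ax.bar(x, a_counts, width=1.0, alpha=0.55, label="aligned", color="#3b6fb6")
        ax.bar(x, u_counts, width=1.0, alpha=0.55, label="unaligned", color="#c0504d")
        ax.set_xlabel("median k-mer abundance")
        ax.set_ylabel("read count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(f"{out_prefix}.hist.png", dpi=120)
        plt.close(fig)
    return result
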
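"""Readers and writers for the external formats the evaluation engine touches.

Everything downstream works on the domain types defined here:
:class:`AlignmentRecord` (one PAF line), :class:`ReadSetStats` (the read-set
denominators), :class:`ContigBinMap` (contig -> bin), :class:`BinQuality`
(CheckM2-style completeness/contamination), and :class:`KrakenReportRow`
(one line of a Kraken2 hierarchical report).

Conventions
-----------
* All alignment coordinates are 0-based half-open, the minimap2 PAF
  convention.
* Read identity is the FASTQ name up to the first whitespace, which is what
  minimap2 writes as the PAF query name.
* Gzip input is detected from the two magic bytes, never from the file
  extension.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "AlignmentRecord",
    "ReadSetStats",
    "ContigBinMap",
    "BinQuality",
    "KrakenReportRow",
    "PafParseError",
    "FastqParseError",
    "read_paf",
    "scan_reads",
    "iter_fastq",
    "read_bin_map",
    "write_bin_map",
    "read_quality_table",
    "read_kraken_report",
    "open_text",
]

GZIP_MAGIC = b"\x1f\x8b"


class PafParseError(ValueError):
    """A PAF line violated the 12-mandatory-field contract."""


class FastqParseError(ValueError):
    """Malformed or ambiguous FASTQ input."""


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One read-to-contig alignment, as parsed from a PAF line.

    Coordinates are 0-based half-open on both query (read) and target
    (contig). ``is_secondary`` reflects the ``tp:A:S`` tag when present.
    """

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    residue_matches: int
    block_length: int
    mapq: int
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"bad query interval [{self.query_start}, {self.query_end}) "
                f"for query {self.query_name!r} of length {self.query_length}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_length):
            raise ValueError(
                f"bad target interval [{self.target_start}, {self.target_end}) "
                f"for target {self.target_name!r} of length {self.target_length}"
            )
        if self.block_length < self.residue_matches:
            raise ValueError(
                f"block_length {self.block_length} < residue_matches "
                f"{self.residue_matches} for query {self.query_name!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def query_span(self) -> int:
        """Number of read bases covered by this alignment (indel-robust)."""
        return self.query_end - self.query_start


@dataclass(slots=True)
class ReadSetStats:
    """Denominators for the aligned read/base percentages.

    ``lengths`` maps each read name (up to first whitespace) to its length
    in bases; ``short_read_count`` counts reads shorter than the k requested
    at scan time (those yield no k-mer window).
    """

    read_count: int
    total_bases: int
    lengths: dict[str, int]
    short_read_count: int = 0

    def __post_init__(self) -> None:
        if self.read_count != len(self.lengths):
            raise ValueError("read_count does not match number of read names")
        if self.total_bases != sum(self.lengths.values()):
            raise ValueError("total_bases does not match sum of lengths")


@dataclass(slots=True)
class ContigBinMap:
    """Mapping of contig name to bin name; absent contigs are unbinned."""

    assignments: dict[str, str] = field(default_factory=dict)

    def bin_of(self, contig: str) -> str | None:
        return self.assignments.get(contig)

    def contigs_of(self, bin_name: str) -> list[str]:
        return [c for c, b in self.assignments.items() if b == bin_name]

    def contig_counts(self) -> dict[str, int]:
        """Number of member contigs per bin."""
        counts: dict[str, int] = {}
        for b in self.assignments.values():
            counts[b] = counts.get(b, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, contig: str) -> bool:
        return contig in self.assignments


@dataclass(frozen=True, slots=True)
class BinQuality:
    """CheckM2-style quality record for one bin.

    Completeness and contamination are on the 0-100 scale; contamination may
    exceed 100 (CheckM2 can report that) and is not clamped.
    """

    bin_name: str
    completeness: float
    contamination: float
    contig_count: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"contamination {self.contamination} < 0")
        if self.contig_count < 1:
            raise ValueError(f"contig_count {self.contig_count} < 1")


@dataclass(slots=True)
class KrakenReportRow:
    """One row of a Kraken2 hierarchical report.

    ``clade_reads`` includes all descendants; ``direct_reads`` only reads
    assigned exactly at this node. ``depth`` is the indentation level (two
    spaces per level) and ``parent`` the nearest preceding shallower row.
    """

    clade_percent: float
    clade_reads: int
    direct_reads: int
    rank_code: str
    taxid: int
    name: str
    depth: int
    parent: "KrakenReportRow | None" = None

    def __post_init__(self) -> None:
        if not (self.clade_reads >= self.direct_reads >= 0):
            raise ValueError(
                f"row {self.name!r}: need clade_reads >= direct_reads >= 0, "
                f"got {self.clade_reads} and {self.direct_reads}"
            )


def open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed file as text (magic-byte sniffing)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_paf(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream :class:`AlignmentRecord` objects from a PAF file.

    Lines must carry at least the 12 mandatory tab-separated fields;
    optional SAM-style tags are scanned only for ``tp:A:`` (alignment type,
    ``S`` marking secondary). An empty file yields an empty stream.

    Raises
    ------
    PafParseError
        On a line with fewer than 12 fields or a non-integer coordinate,
        naming the offending line number.
    """
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise PafParseError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                rec = AlignmentRecord(
                    query_name=fields[0],
                    query_length=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_name=fields[5],
                    target_length=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    residue_matches=int(fields[9]),
                    block_length=int(fields[10]),
                    mapq=int(fields[11]),
                    is_secondary=any(
                        tag.startswith("tp:A:") and tag[5:6] == "S"
                        for tag in fields[12:]
                    ),
                )
            except ValueError as exc:
                raise PafParseError(f"{path}: line {lineno}: {exc}") from exc
            yield rec


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(name, sequence, quality)`` from FASTQ, name cut at whitespace."""
    with open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split(None, 1)[0], seq, qual
        except ValueError as exc:  # Biopython signals truncated records this way
            raise FastqParseError(f"{path}: {exc}") from exc


def scan_reads(path: str | Path, k_min: int = 0) -> ReadSetStats:
    """Single pass over a FASTQ file collecting the per-read lengths.

    ``k_min`` flags reads too short to contribute a k-mer window of that
    size; the count is carried on the returned stats for the abundance
    profiler. Duplicate read names are an error: read identity must be
    unambiguous to join alignments back to reads.
    """
    lengths: dict[str, int] = {}
    total = 0
    short = 0
    for name, seq, _ in iter_fastq(path):
        if name in lengths:
            raise FastqParseError(f"{path}: duplicate read name {name!r}")
        n = len(seq)
        lengths[name] = n
        total += n
        if n < k_min:
            short += 1
    return ReadSetStats(
        read_count=len(lengths),
        total_bases=total,
        lengths=lengths,
        short_read_count=short,
    )


def read_bin_map(source: str | Path) -> ContigBinMap:
    """Load a contig -> bin assignment.

    Two dialects are accepted: a two-column TSV (contig, bin; no header
    required) or a directory of per-bin FASTA files, each file being one bin
    named by its stem with its sequence headers as the member contigs.
    A contig assigned to two bins is an error.
    """
    source = Path(source)
    assignments: dict[str, str] = {}

    def assign(contig: str, bin_name: str) -> None:
        prev = assignments.get(contig)
        if prev is not None and prev != bin_name:
            raise ValueError(
                f"contig {contig!r} assigned to both {prev!r} and {bin_name!r}"
            )
        assignments[contig] = bin_name

    if source.is_dir():
        fasta_files = sorted(
            p for p in source.iterdir() if p.suffix.lower() in (".fa", ".fasta")
        )
        for fp in fasta_files:
            with open_text(fp) as fh:
                for title, _seq in SimpleFastaParser(fh):
                    assign(title.split(None, 1)[0], fp.stem)
    else:
        with open_text(source) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(
                        f"{source}: line {lineno}: expected two tab-separated "
                        "columns (contig, bin)"
                    )
                assign(parts[0], parts[1])
    return ContigBinMap(assignments)


def write_bin_map(bin_map: ContigBinMap, path: str | Path) -> None:
    """Write a contig -> bin assignment as two-column TSV (round-trippable)."""
    with open(path, "wt") as fh:
        for contig, bin_name in bin_map.assignments.items():
            fh.write(f"{contig}\t{bin_name}\n")


def read_quality_table(
    path: str | Path,
    contig_counts: Mapping[str, int] | None = None,
) -> list[BinQuality]:
    """Parse a CheckM2-style quality report.

    The header must contain Name, Completeness and Contamination columns
    (case-insensitive; extra columns ignored). Contig counts come from an
    optional ``Contig_Count`` column or, preferably, from the bin map via
    ``contig_counts``; bins absent from both default to 1.
    """
    with open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty quality table")
        cols = [c.strip().lower() for c in header.split("\t")]
        try:
            i_name = cols.index("name")
            i_comp = cols.index("completeness")
            i_cont = cols.index("contamination")
        except ValueError:
            raise ValueError(
                f"{path}: header must contain Name, Completeness and "
                f"Contamination; found columns {cols}"
            ) from None
        i_count = cols.index("contig_count") if "contig_count" in cols else None

        out: list[BinQuality] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name = parts[i_name]
            try:
                comp = float(parts[i_comp])
                cont = float(parts[i_cont])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric completeness or "
                    f"contamination ({exc})"
                ) from exc
            if i_count is not None:
                count = int(parts[i_count])
            elif contig_counts is not None and name in contig_counts:
                count = contig_counts[name]
            else:
                count = 1
            out.append(BinQuality(name, comp, cont, count))
    return out


def read_kraken_report(path: str | Path) -> list[KrakenReportRow]:
    """Parse a 6-column Kraken2 report, reconstructing the taxonomy tree.

    The name column is indented two spaces per depth level; each row's
    parent is the nearest preceding row with smaller depth. Rows violating
    the containment invariants (child clade exceeding its parent, a depth
    jump of more than one level) are rejected.
    """
    rows: list[KrakenReportRow] = []
    stack: list[KrakenReportRow] = []  # ancestors of the current row
    child_sums: dict[int, int] = {}  # id(row) -> sum of children clade_reads
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 tab-separated columns"
                )
            raw_name = parts[5]
            stripped = raw_name.lstrip(" ")
            indent = len(raw_name) - len(stripped)
            if indent % 2 != 0:
                raise ValueError(
                    f"{path}: line {lineno}: odd indentation ({indent} spaces)"
                )
            depth = indent // 2
            try:
                row = KrakenReportRow(
                    clade_percent=float(parts[0]),
                    clade_reads=int(parts[1]),
                    direct_reads=int(parts[2]),
                    rank_code=parts[3],
                    taxid=int(parts[4]),
                    name=stripped,
                    depth=depth,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc

            while stack and stack[-1].depth >= depth:
                stack.pop()
            if depth > (stack[-1].depth + 1 if stack else 0):
                raise ValueError(
                    f"{path}: line {lineno}: depth jumps from "
                    f"{stack[-1].depth if stack else -1} to {depth}"
                )
            if stack:
                row.parent = stack[-1]
                child_sums[id(row.parent)] = (
                    child_sums.get(id(row.parent), 0) + row.clade_reads
                )
                if child_sums[id(row.parent)] > row.parent.clade_reads:
                    raise ValueError(
                        f"{path}: line {lineno}: children of "
                        f"{row.parent.name!r} sum to more than its clade_reads"
                    )
            stack.append(row)
            rows.append(row)
    return rows
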
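"""Deterministic synthetic datasets with analytically known metric values.

The generator emulates, at desk scale, the artefacts a real evaluation run
consumes: assembled contigs, a binning of those contigs, a CheckM2-style
quality table, a HiFi-like read set, and the read-to-contig alignments.
Aligned reads are exact substrings of their contigs and the generator
emits the PAF itself with the true coordinates, so the expected value of
every metric is closed-form — no aligner, no error model. Real data differ
in exactly those respects (sequencing error, chimeric and clipped
alignments, repeat-induced multi-mapping); what the fixtures certify is the
accounting, not aligner behaviour.

One integer seed drives a single deterministic stream: the same seed
produces a byte-identical file bundle.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .bins import QualityTier, classify_tier
from .io import BinQuality

__all__ = [
    "BinSpec",
    "FixtureConfig",
    "FixtureTruth",
    "generate_sample",
    "generate_kraken_report",
]

_BASES = "ACGT"


@dataclass(frozen=True, slots=True)
class BinSpec:
    """One synthetic bin: member contig count and its quality estimates."""

    contig_count: int
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if self.contig_count < 1:
            raise ValueError("contig_count must be >= 1")
        if not (0 <= self.completeness <= 100):
            raise ValueError("completeness outside [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination < 0")


@dataclass(slots=True)
class FixtureConfig:
    """Study conditions for one synthetic sample.

    Defaults sketch a small community whose binning spans every quality
    tier: one single-contig near-complete bin, one high-, one medium- and
    one low-quality bin, plus unbinned contigs, with a quarter of the reads
    left unaligned — the regime where binning-aware metrics are
    informative. Read lengths are kilobase-scale (long-read-like but small
    enough for sub-second tests).
    """

    seed: int = 0
    bins: tuple[BinSpec, ...] = (
        BinSpec(1, 99.5, 0.5),   # near complete
        BinSpec(2, 95.0, 2.0),   # high
        BinSpec(2, 70.0, 8.0),   # medium
        BinSpec(2, 30.0, 15.0),  # low
    )
    unbinned_contigs: int = 2
    contig_length_range: tuple[int, int] = (3000, 5000)
    reads_per_contig: int = 4
    read_length_range: tuple[int, int] = (800, 2000)
    unaligned_reads: int = 12
    partial_coverage_fraction: float = 0.0
    partial_coverage: float = 0.5  # covered query fraction of a partial read

    def validate(self) -> None:
        if self.unbinned_contigs < 0 or self.unaligned_reads < 0:
            raise ValueError("counts must be >= 0")
        if self.reads_per_contig < 0:
            raise ValueError("reads_per_contig must be >= 0")
        lo_c, hi_c = self.contig_length_range
        lo_r, hi_r = self.read_length_range
        if not (1 <= lo_c <= hi_c) or not (1 <= lo_r <= hi_r):
            raise ValueError("length ranges must satisfy 1 <= lo <= hi")
        if hi_r > lo_c:
            raise ValueError(
                f"max read length {hi_r} exceeds min contig length {lo_c}: "
                "reads must fit inside their contig"
            )
        if not (0.0 <= self.partial_coverage_fraction <= 1.0):
            raise ValueError("partial_coverage_fraction outside [0, 1]")
        if not (0.0 < self.partial_coverage <= 1.0):
            raise ValueError("partial_coverage outside (0, 1]")


@dataclass(slots=True)
class FixtureTruth:
    """Ground truth emitted alongside a sample bundle."""

    per_read: dict[str, dict]  # name -> {tier, length, covered intervals}
    expected_report: dict[str, dict]  # category label -> counts/percents
    aligned_read_percent: float
    aligned_base_percent: float
    total_reads: int
    total_bases: int


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def generate_sample(
    config: FixtureConfig, out_dir: str | Path
) -> tuple[FixtureTruth, dict[str, Path]]:
    """Write a complete sample bundle and its ground truth.

    Emits ``contigs.fasta``, ``reads.fastq``, ``truth.paf``, ``bins.tsv``,
    ``quality.tsv`` and ``truth.json`` under ``out_dir``. Aligned reads are
    exact substrings of contigs; each gets one PAF record with the true
    coordinates (query interval shortened for partial-coverage reads).
    Unaligned reads are fresh random sequences absent from the PAF.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)

    # --- contigs and bins ------------------------------------------------
    contigs: dict[str, str] = {}
    bin_of: dict[str, str] = {}
    qualities: list[BinQuality] = []
    tier_of_bin: dict[str, QualityTier] = {}
    n_contig = 0

    def new_contig() -> str:
        nonlocal n_contig
        n_contig += 1
        name = f"c{n_contig:04d}"
        contigs[name] = _random_seq(rng, rng.randint(*config.contig_length_range))
        return name

    for i, spec in enumerate(config.bins, start=1):
        bin_name = f"bin{i:03d}"
        for _ in range(spec.contig_count):
            bin_of[new_contig()] = bin_name
        q = BinQuality(bin_name, spec.completeness, spec.contamination, spec.contig_count)
        qualities.append(q)
        tier_of_bin[bin_name] = classify_tier(q)
    for _ in range(config.unbinned_contigs):
        new_contig()

    def tier_of_contig(name: str) -> QualityTier:
        b = bin_of.get(name)
        return tier_of_bin[b] if b is not None else QualityTier.UNBINNED

    # --- reads and true alignments ---------------------------------------
    reads: list[tuple[str, str]] = []  # (name, seq)
    paf_lines: list[str] = []
    per_read: dict[str, dict] = {}
    n_read = 0

    for contig_name, contig_seq in contigs.items():
        tier = tier_of_contig(contig_name)
        for _ in range(config.reads_per_contig):
            n_read += 1
            read_name = f"r{n_read:05d}"
            length = rng.randint(*config.read_length_range)
            start = rng.randint(0, len(contig_seq) - length)
            seq = contig_seq[start : start + length]
            partial = rng.random() < config.partial_coverage_fraction
            covered = (
                max(1, int(length * config.partial_coverage)) if partial else length
            )
            paf_lines.append(
                "\t".join(
                    map(
                        str,
                        (
                            read_name, length, 0, covered, "+",
                            contig_name, len(contig_seq),
                            start, start + covered,
                            covered, covered, 60,
                        ),
                    )
                )
                + "\ttp:A:P"
            )
            reads.append((read_name, seq))
            per_read[read_name] = {
                "tier": tier.label,
                "length": length,
                "covered": [[0, covered]],
            }

    for _ in range(config.unaligned_reads):
        n_read += 1
        read_name = f"r{n_read:05d}"
        length = rng.randint(*config.read_length_range)
        reads.append((read_name, _random_seq(rng, length)))
        per_read[read_name] = {
            "tier": QualityTier.UNALIGNED.label,
            "length": length,
            "covered": [],
        }

    # --- closed-form expected report --------------------------------------
    total_reads = len(reads)
    total_bases = sum(len(s) for _, s in reads)
    expected: dict[str, dict] = {}
    for tier in (
        QualityTier.NEAR_COMPLETE, QualityTier.HIGH, QualityTier.MEDIUM,
        QualityTier.LOW, QualityTier.UNBINNED, QualityTier.UNALIGNED,
    ):
        expected[tier.label] = {"read_count": 0, "base_count": 0}
    for info in per_read.values():
        expected[info["tier"]]["read_count"] += 1
        covered = sum(e - s for s, e in info["covered"])
        expected[info["tier"]]["base_count"] += covered
        expected[QualityTier.UNALIGNED.label]["base_count"] += info["length"] - covered
    for cat in expected.values():
        cat["read_percent"] = 100.0 * cat["read_count"] / total_reads
        cat["base_percent"] = 100.0 * cat["base_count"] / total_bases
    aligned_reads = total_reads - expected[QualityTier.UNALIGNED.label]["read_count"]
    aligned_bases = sum(
        sum(e - s for s, e in info["covered"]) for info in per_read.values()
    )
    truth = FixtureTruth(
        per_read=per_read,
        expected_report=expected,
        aligned_read_percent=100.0 * aligned_reads / total_reads,
        aligned_base_percent=100.0 * aligned_bases / total_bases,
        total_reads=total_reads,
        total_bases=total_bases,
    )

    # --- write the bundle --------------------------------------------------
    paths = {
        "contigs": out_dir / "contigs.fasta",
        "reads": out_dir / "reads.fastq",
        "paf": out_dir / "truth.paf",
        "bins": out_dir / "bins.tsv",
        "quality": out_dir / "quality.tsv",
        "truth": out_dir / "truth.json",
    }
    with open(paths["contigs"], "wt") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    with open(paths["reads"], "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    with open(paths["paf"], "wt") as fh:
        fh.write("".join(line + "\n" for line in paf_lines))
    with open(paths["bins"], "wt") as fh:
        for contig_name, bin_name in bin_of.items():
            fh.write(f"{contig_name}\t{bin_name}\n")
    with open(paths["quality"], "wt") as fh:
        fh.write("Name\tCompleteness\tContamination\tContig_Count\n")
        for q in qualities:
            fh.write(
                f"{q.bin_name}\t{q.completeness}\t{q.contamination}\t{q.contig_count}\n"
            )
    with open(paths["truth"], "wt") as fh:
        json.dump(
            {
                "config": {
                    **asdict(config),
                    "bins": [asdict(b) for b in config.bins],
                },
                "per_read": truth.per_read,
                "expected_report": truth.expected_report,
                "aligned_read_percent": truth.aligned_read_percent,
                "aligned_base_percent": truth.aligned_base_percent,
                "total_reads": truth.total_reads,
                "total_bases": truth.total_bases,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return truth, paths


def generate_kraken_report(
    profile: Sequence[tuple[Sequence[str], Sequence[str], int]],
    out_path: str | Path,
    unclassified: int = 0,
) -> None:
    """Write a Kraken2-style report from a taxonomy profile.

    ``profile`` lists ``(path_of_names, rank_codes, direct_reads)`` where
    the direct count applies to the terminal node of the path; ancestors
    are created (with direct count 0) as needed. Clade read counts are
    subtree sums, indentation encodes depth, and percentages are computed
    from the grand total (classified + unclassified). A path whose rank
    codes conflict with an earlier occurrence of the same node is an error.
    """
    # node key = tuple of names from the root; values mutable
    nodes: dict[tuple[str, ...], dict] = {}
    order: list[tuple[str, ...]] = []

    for names, ranks, direct in profile:
        names, ranks = tuple(names), tuple(ranks)
        if len(names) != len(ranks):
            raise ValueError(f"path {names} and rank codes {ranks} differ in length")
        if direct < 0:
            raise ValueError("direct read counts must be >= 0")
        for i in range(1, len(names) + 1):
            key = names[:i]
            rank = ranks[i - 1]
            node = nodes.get(key)
            if node is None:
                nodes[key] = {"rank": rank, "direct": 0}
                order.append(key)
            elif node["rank"] != rank:
                raise ValueError(
                    f"node {'/'.join(key)} listed with conflicting rank codes "
                    f"{node['rank']!r} and {rank!r}"
                )
        nodes[names]["direct"] += direct

    # clade reads = subtree sums (longer keys are descendants by prefix)
    for key in nodes:
        nodes[key]["clade"] = sum(
            n["direct"] for k, n in nodes.items() if k[: len(key)] == key
        )
    total = unclassified + sum(n["direct"] for n in nodes.values())

    # DFS order: sort children under each parent by first appearance
    def dfs(prefix: tuple[str, ...]) -> list[tuple[str, ...]]:
        children = [k for k in order if len(k) == len(prefix) + 1 and k[: len(prefix)] == prefix]
        out = []
        for child in children:
            out.append(child)
            out.extend(dfs(child))
        return out

    with open(out_path, "wt") as fh:

        def write_row(pct_reads: int, direct: int, rank: str, taxid: int, name: str, depth: int) -> None:
            pct = 100.0 * pct_reads / total if total else 0.0
            fh.write(
                f"{pct:.2f}\t{pct_reads}\t{direct}\t{rank}\t{taxid}\t"
                f"{'  ' * depth}{name}\n"
            )

        if unclassified or not nodes:
            write_row(unclassified, unclassified, "U", 0, "unclassified", 0)
        taxid = 0
        for key in dfs(()):
            taxid += 1
            node = nodes[key]
            write_row(
                node["clade"], node["direct"], node["rank"], taxid, key[-1], len(key) - 1
            )
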
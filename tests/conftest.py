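"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: per-base
labelling with plain Python lists for the alignment metrics, and string
enumeration for k-mer counting. They are the reference the fast
implementations are checked against.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pytest
from hypothesis import settings

from maglens.bins import QualityTier
from maglens.io import AlignmentRecord, ReadSetStats

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

CONTIG_TIERS = [
    QualityTier.NEAR_COMPLETE,
    QualityTier.HIGH,
    QualityTier.MEDIUM,
    QualityTier.LOW,
    QualityTier.UNBINNED,
]


@dataclass
class RandomInstance:
    """A small random metrics problem plus everything needed to solve it."""

    read_stats: ReadSetStats
    records: list[AlignmentRecord]
    tier_of_contig: dict[str, QualityTier]


def make_instance(
    rng: random.Random,
    max_reads: int = 20,
    max_contigs: int = 5,
    max_alignments_per_read: int = 4,
) -> RandomInstance:
    """Random instance: short reads, few contigs, random tier assignment."""
    n_reads = rng.randint(1, max_reads)
    n_contigs = rng.randint(1, max_contigs)
    contig_len = 500
    contigs = {
        f"c{j}": rng.choice(CONTIG_TIERS) for j in range(n_contigs)
    }
    lengths: dict[str, int] = {}
    records: list[AlignmentRecord] = []
    for i in range(n_reads):
        name = f"r{i}"
        length = rng.randint(1, 100)
        lengths[name] = length
        for _ in range(rng.randint(0, max_alignments_per_read)):
            qs = rng.randint(0, length - 1)
            qe = rng.randint(qs + 1, length)
            target = f"c{rng.randrange(n_contigs)}"
            records.append(
                AlignmentRecord(
                    query_name=name, query_length=length,
                    query_start=qs, query_end=qe, strand="+",
                    target_name=target, target_length=contig_len,
                    target_start=0, target_end=min(qe - qs, contig_len),
                    residue_matches=qe - qs, block_length=qe - qs,
                    mapq=60, is_secondary=rng.random() < 0.2,
                )
            )
    stats = ReadSetStats(
        read_count=n_reads, total_bases=sum(lengths.values()), lengths=lengths
    )
    return RandomInstance(stats, records, contigs)


def brute_force_categories(
    inst: RandomInstance, min_length: int = 0, count_secondary: bool = True
) -> dict[QualityTier, dict[str, int]]:
    """Per-base brute force: label every base with the best covering tier.

    Independent of the implementation: builds an explicit per-position
    label array for every read and counts from it.
    """
    out = {
        t: {"read_count": 0, "base_count": 0}
        for t in CONTIG_TIERS + [QualityTier.UNALIGNED]
    }
    by_read: dict[str, list[AlignmentRecord]] = {
        name: [] for name in inst.read_stats.lengths
    }
    for rec in inst.records:
        if not count_secondary and rec.is_secondary:
            continue
        if rec.query_end - rec.query_start < min_length:
            continue
        by_read[rec.query_name].append(rec)

    for name, length in inst.read_stats.lengths.items():
        labels = [QualityTier.UNALIGNED] * length
        best = QualityTier.UNALIGNED
        for rec in by_read[name]:
            tier = inst.tier_of_contig[rec.target_name]
            best = max(best, tier)
            for pos in range(rec.query_start, rec.query_end):
                labels[pos] = max(labels[pos], tier)
        out[best]["read_count"] += 1
        for lab in labels:
            out[lab]["base_count"] += 1
    return out


def brute_force_kmer_counts(reads: list[str], k: int) -> dict[str, int]:
    """Enumerate every window; canonicalize by explicit string comparison."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts: dict[str, int] = {}
    for seq in reads:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(c not in comp for c in w):
                continue
            rc = "".join(comp[c] for c in reversed(w))
            key = w if w <= rc else rc
            counts[key] = counts.get(key, 0) + 1
    return counts


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture()
def sample_bundle(tmp_path):
    """Default synthetic sample bundle with its ground truth."""
    from maglens.fixtures import FixtureConfig, generate_sample

    truth, paths = generate_sample(FixtureConfig(seed=11), tmp_path / "sample")
    return truth, paths
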
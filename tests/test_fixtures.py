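"""Synthetic sample generator: determinism, parseability, truth recovery."""

import hashlib
import json

import pytest

from maglens import io as mio
from maglens.bins import REPORT_TIERS
from maglens.fixtures import (
    BinSpec,
    FixtureConfig,
    generate_kraken_report,
    generate_sample,
)
from maglens.pipeline import compute_report


def bundle_digests(paths):
    return {
        key: hashlib.sha256(p.read_bytes()).hexdigest()
        for key, p in paths.items()
    }


def test_same_seed_gives_byte_identical_bundle(tmp_path):
    _, p1 = generate_sample(FixtureConfig(seed=42), tmp_path / "a")
    _, p2 = generate_sample(FixtureConfig(seed=42), tmp_path / "b")
    assert bundle_digests(p1) == bundle_digests(p2)
    _, p3 = generate_sample(FixtureConfig(seed=43), tmp_path / "c")
    assert bundle_digests(p1) != bundle_digests(p3)


def test_generated_paf_is_parseable_with_one_record_per_placement(tmp_path):
    config = FixtureConfig(seed=5)
    truth, paths = generate_sample(config, tmp_path)
    records = list(mio.read_paf(paths["paf"]))
    n_aligned_reads = sum(
        1 for info in truth.per_read.values() if info["covered"]
    )
    assert len(records) == n_aligned_reads
    assert len(records) == sum(line != "" for line in paths["paf"].read_text().splitlines())


def test_truth_json_matches_recomputed_report(tmp_path):
    truth, paths = generate_sample(FixtureConfig(seed=17), tmp_path)
    stored = json.loads(paths["truth"].read_text())
    report, _, _ = compute_report(
        paths["paf"], paths["reads"], paths["bins"], paths["quality"]
    )
    for tier in REPORT_TIERS:
        cat = report.categories[tier]
        expected = stored["expected_report"][tier.label]
        assert cat.read_count == expected["read_count"]
        assert cat.base_count == expected["base_count"]


def test_three_to_one_config_yields_exact_75_percent(tmp_path):
    """3 aligned : 1 unaligned at equal read length -> exactly 75 / 75."""
    config = FixtureConfig(
        seed=1,
        bins=(BinSpec(1, 95.0, 2.0),),
        unbinned_contigs=0,
        reads_per_contig=3,
        read_length_range=(1000, 1000),
        unaligned_reads=1,
        partial_coverage_fraction=0.0,
    )
    truth, _ = generate_sample(config, tmp_path)
    assert truth.aligned_read_percent == 75.0
    assert truth.aligned_base_percent == 75.0


def test_no_partial_coverage_means_full_coverage(tmp_path):
    truth, _ = generate_sample(
        FixtureConfig(seed=2, partial_coverage_fraction=0.0), tmp_path
    )
    for info in truth.per_read.values():
        if info["covered"]:
            assert sum(e - s for s, e in info["covered"]) == info["length"]


def test_partial_coverage_reads_cover_half(tmp_path):
    truth, _ = generate_sample(
        FixtureConfig(seed=3, partial_coverage_fraction=1.0, partial_coverage=0.5),
        tmp_path,
    )
    for info in truth.per_read.values():
        if info["covered"]:
            covered = sum(e - s for s, e in info["covered"])
            assert covered == int(info["length"] * 0.5)


def test_aligned_reads_are_exact_substrings_of_their_contigs(tmp_path):
    _, paths = generate_sample(FixtureConfig(seed=23), tmp_path)
    contigs = {}
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(paths["contigs"]) as fh:
        for name, seq in SimpleFastaParser(fh):
            contigs[name] = seq
    reads = {name: seq for name, seq, _ in mio.iter_fastq(paths["reads"])}
    for rec in mio.read_paf(paths["paf"]):
        read_seq = reads[rec.query_name]
        contig_seq = contigs[rec.target_name]
        assert contig_seq[rec.target_start : rec.target_end] == read_seq[
            rec.query_start : rec.query_end
        ]


def test_oversized_reads_rejected():
    config = FixtureConfig(
        contig_length_range=(1000, 2000), read_length_range=(500, 3000)
    )
    with pytest.raises(ValueError, match="exceeds min contig length"):
        config.validate()


class TestKrakenGenerator:
    def test_clade_reads_are_subtree_sums(self, tmp_path):
        path = tmp_path / "a.kreport"
        generate_kraken_report(
            [
                (("root", "Bacteria"), ("R", "D"), 20),
                (("root", "Bacteria", "PhylumA"), ("R", "D", "P"), 30),
            ],
            path,
        )
        rows = mio.read_kraken_report(path)
        bacteria = next(r for r in rows if r.name == "Bacteria")
        assert bacteria.clade_reads == 50
        assert bacteria.direct_reads == 20

    def test_empty_profile_with_unclassified_gives_single_u_row(self, tmp_path):
        path = tmp_path / "u.kreport"
        generate_kraken_report([], path, unclassified=10)
        (row,) = mio.read_kraken_report(path)
        assert row.rank_code == "U" and row.clade_reads == 10

    def test_roundtrip_preserves_profile(self, tmp_path):
        profile = [
            (("root", "Bacteria"), ("R", "D"), 5),
            (("root", "Bacteria", "PhylumA"), ("R", "D", "P"), 7),
            (("root", "Bacteria", "PhylumB"), ("R", "D", "P"), 3),
            (("root", "Archaea"), ("R", "D"), 2),
        ]
        path = tmp_path / "rt.kreport"
        generate_kraken_report(profile, path, unclassified=4)
        rows = mio.read_kraken_report(path)
        directs = {r.name: r.direct_reads for r in rows if r.direct_reads}
        assert directs == {
            "unclassified": 4, "Bacteria": 5, "PhylumA": 7, "PhylumB": 3,
            "Archaea": 2,
        }
        total_direct = sum(r.direct_reads for r in rows)
        root = next(r for r in rows if r.name == "root")
        assert total_direct == root.clade_reads + 4

    def test_conflicting_rank_codes_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="conflicting rank codes"):
            generate_kraken_report(
                [
                    (("root", "Bacteria"), ("R", "D"), 1),
                    (("root", "Bacteria"), ("R", "K"), 1),
                ],
                tmp_path / "x.kreport",
            )
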
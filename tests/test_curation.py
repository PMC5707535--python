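"""Coverage profiles, bin splitting/merging, pairing, and classification."""

import numpy as np
import pytest

from cocktailscope import seq_synth as ss
from cocktailscope.binning import Bin
from cocktailscope.curation import (
    CoverageProfile,
    abundance_table,
    classify,
    depth_profile,
    internal_overlap,
    merge_bins,
    pair_bins,
    split_bin,
)


def profile_from_depths(depths: dict[str, float], length: int = 12_000) -> CoverageProfile:
    return CoverageProfile(
        contig_mean=dict(depths),
        contig_sd={c: 0.0 for c in depths},
        contig_len={c: length for c in depths},
    )


class TestDepthProfile:
    def test_no_reads_gives_zero_depth(self, small_db):
        contigs = [("c0", small_db[0].sequence[:10_000])]
        prof = depth_profile(contigs, reads=([], []))
        assert prof.contig_mean["c0"] == 0.0 and prof.n_mapped == 0

    def test_uniform_placement_matches_arithmetic(self, rng):
        db, _ = ss.generate_phage_db(1, (10_000, 10_000), seed=51)
        contig = db[0].sequence
        reads = []
        for i in range(100):
            start = int(rng.integers(0, 9_900))
            reads.append((f"r{i}", contig[start : start + 100], "I" * 100))
        prof = depth_profile([("c0", contig)], reads=(reads, []))
        # 100 reads x 100 bp / 10,000 bp = 1.0
        assert prof.contig_mean["c0"] == pytest.approx(1.0, abs=0.1)
        assert prof.n_mapped == 100

    def test_bin_mean_is_length_weighted(self):
        prof = CoverageProfile(
            contig_mean={"a": 10.0, "b": 20.0},
            contig_sd={"a": 0.0, "b": 0.0},
            contig_len={"a": 1_000, "b": 3_000},
        )
        assert prof.bin_mean(["a", "b"]) == pytest.approx(17.5)

    def test_sam_ingest_matches_manual_depth(self, tmp_path):
        ref = "ACGT" * 50  # 200 bp
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:c0\tLN:200\n"
            "r1\t0\tc0\t1\t60\t100M\t*\t0\t0\t" + ref[:100] + "\t*\n"
            "r2\t0\tc0\t51\t60\t100M\t*\t0\t0\t" + ref[50:150] + "\t*\n"
        )
        prof = depth_profile([("c0", ref)], alignments=str(sam))
        assert prof.n_mapped == 2
        assert prof.contig_mean["c0"] == pytest.approx(200 / 200)
        assert prof.depth_arrays["c0"][60] == 2 and prof.depth_arrays["c0"][180] == 0


class TestSplitBin:
    def test_uniform_depths_not_split(self):
        b = Bin("bin_1", ["a", "b", "c"], 36_000)
        prof = profile_from_depths({"a": 10.0, "b": 10.5, "c": 9.8})
        assert split_bin(b, prof) == [b]

    def test_split_at_largest_depth_gap(self):
        ids = ["a", "b", "c", "d", "e", "f"]
        depths = dict(zip(ids, [12.0, 12.0, 13.0, 17.0, 17.0, 18.0]))
        b = Bin("bin_1", ids, 72_000)
        parts = split_bin(b, profile_from_depths(depths))
        groups = sorted(sorted(p.contig_ids) for p in parts)
        assert groups == [["a", "b", "c"], ["d", "e", "f"]]
        assert all(p.provenance == "split" for p in parts)

    def test_undersized_group_reattached_to_nearest_depth(self):
        depths = {"a": 10.0, "b": 10.2, "c": 30.0}
        b = Bin("bin_1", list(depths), 36_000)
        prof = CoverageProfile(
            contig_mean=depths,
            contig_sd={c: 0.0 for c in depths},
            contig_len={"a": 12_000, "b": 12_000, "c": 4_000},
        )
        parts = split_bin(b, prof)
        # "c" alone is below the bin floor: it must rejoin a sibling
        assert sorted(c for p in parts for c in p.contig_ids) == ["a", "b", "c"]
        assert all(p.total_bp >= 10_000 for p in parts)


class TestMergeBins:
    def _setup(self, seed=71):
        db, _ = ss.generate_phage_db(2, (30_000, 36_000), seed=seed)
        g = db[0].sequence
        third = len(g) // 3
        contig_seqs = {
            "x0": g[:third],
            "x1": g[third : 2 * third],
            "x2": g[2 * third :],
            "y0": db[1].sequence[:12_000],
        }
        bins = [
            Bin("bin_1", ["x0"], third),
            Bin("bin_2", ["x1"], third),
            Bin("bin_3", ["x2"], len(g) - 2 * third),
            Bin("bin_4", ["y0"], 12_000),
        ]
        prof = CoverageProfile(
            contig_mean={"x0": 20.0, "x1": 21.0, "x2": 19.5, "y0": 20.0},
            contig_sd={c: 0.0 for c in contig_seqs},
            contig_len={c: len(s) for c, s in contig_seqs.items()},
        )
        return bins, prof, contig_seqs

    def test_same_reference_similar_depth_merge(self):
        bins, prof, seqs = self._setup()
        refs = {"bin_1": "refA", "bin_2": "refA", "bin_3": "refA", "bin_4": "refB"}
        merged = merge_bins(bins, refs, prof, seqs)
        assert len(merged) == 2
        big = max(merged, key=lambda b: b.total_bp)
        assert sorted(big.contig_ids) == ["x0", "x1", "x2"]
        assert big.provenance == "merged"

    def test_different_references_not_merged(self):
        bins, prof, seqs = self._setup()
        refs = {"bin_1": "refA", "bin_2": "refB", "bin_3": "refC", "bin_4": "refD"}
        assert len(merge_bins(bins, refs, prof, seqs)) == 4

    def test_depth_mismatch_blocks_merge(self):
        bins, prof, seqs = self._setup()
        prof.contig_mean["x1"] = 60.0
        refs = {b.id: "refA" for b in bins}
        merged = merge_bins(bins, refs, prof, seqs)
        assert not any(
            set(b.contig_ids) >= {"x0", "x1"} for b in merged
        )

    def test_overlapping_contigs_block_merge(self):
        db, _ = ss.generate_phage_db(1, (30_000, 30_000), seed=72)
        g = db[0].sequence
        seqs = {"x0": g[:16_000], "x1": g[14_000:]}  # 2 kb shared overlap
        bins = [Bin("bin_1", ["x0"], 16_000), Bin("bin_2", ["x1"], len(g) - 14_000)]
        prof = CoverageProfile(
            contig_mean={"x0": 20.0, "x1": 20.0},
            contig_sd={"x0": 0.0, "x1": 0.0},
            contig_len={c: len(s) for c, s in seqs.items()},
        )
        refs = {"bin_1": "refA", "bin_2": "refA"}
        assert len(merge_bins(bins, refs, prof, seqs)) == 2

    def test_internal_overlap_detection(self):
        db, _ = ss.generate_phage_db(1, (30_000, 30_000), seed=73)
        g = db[0].sequence
        assert internal_overlap([("a", g[:10_000]), ("b", g[8_000:18_000])])
        assert not internal_overlap([("a", g[:10_000]), ("b", g[10_000:20_000])])


class TestPairBins:
    def test_sample_paired_with_itself(self, small_db):
        bins = {
            f"bin_{i}": [(f"{p.id}_c0", p.sequence)] for i, p in enumerate(small_db)
        }
        matches = pair_bins(bins, bins, compute_reciprocal=False)
        assert len(matches) == len(bins)
        assert all(m.bin_a == m.bin_b for m in matches)
        assert all(m.ani_a_to_b > 99.0 for m in matches)

    def test_label_swap_permutes_but_preserves_matches(self, small_db):
        bins_a = {f"a{i}": [(f"pa{i}", p.sequence)] for i, p in enumerate(small_db[:3])}
        bins_b = {
            f"b{i}": [(f"pb{i}", ss.derive_relative(p, 0.02, seed=i).sequence)]
            for i, p in enumerate(small_db[:3])
        }
        m1 = pair_bins(bins_a, bins_b, compute_reciprocal=False)
        m2 = pair_bins(bins_b, bins_a, compute_reciprocal=False)
        assert {(m.bin_a, m.bin_b) for m in m1} == {(m.bin_b, m.bin_a) for m in m2}

    def test_unrelated_bins_do_not_match(self, small_db):
        bins_a = {"a0": [("pa0", small_db[0].sequence)]}
        bins_b = {"b0": [("pb0", small_db[1].sequence)]}
        assert pair_bins(bins_a, bins_b, compute_reciprocal=False) == []


class TestClassify:
    REF_LEN = 100_000

    def test_near_complete_high_ani_with_counterpart(self):
        assert classify(96_000, [96_000], 96.86, self.REF_LEN, True) == 1

    def test_near_complete_high_ani_without_counterpart(self):
        assert classify(96_000, [96_000], 96.86, self.REF_LEN, False) == 2

    def test_partial_with_counterpart(self):
        assert classify(40_000, [40_000], 22.1, self.REF_LEN, True) == 3

    def test_high_ani_but_short_bin_is_partial(self):
        # 80% of the reference stays partial despite ANI 75
        assert classify(80_000, [80_000], 75.359, self.REF_LEN, False) == 4

    def test_collapsed_bin(self):
        assert classify(
            115_000, [60_000, 55_000], 90.0, self.REF_LEN, False,
            has_internal_overlap=True,
        ) == 5

    def test_oversized_without_overlap_is_not_collapsed(self):
        assert classify(115_000, [115_000], 90.0, self.REF_LEN, False) == 2

    def test_low_ani_special_case(self):
        assert classify(11_313, [11_313], 0.704, self.REF_LEN, False) == 6

    def test_fragmented_special_case(self):
        lengths = [3_000] * 26
        assert classify(sum(lengths), lengths, 42.11, self.REF_LEN, True) == 6

    def test_many_contigs_with_one_long_is_not_fragmented(self):
        lengths = [3_000] * 25 + [8_000]
        assert classify(sum(lengths), lengths, 75.0, self.REF_LEN, False) != 6


class TestAbundanceTable:
    def test_normalization_and_log_handling(self):
        df = abundance_table(
            {"b1": {"s1": 50.0, "s2": 0.0}},
            {"s1": 1_000_000, "s2": 2_000_000},
        )
        row = df.iloc[0]
        assert row["normcov_s1"] == pytest.approx(5e-5)
        assert row["log10_s1"] == pytest.approx(np.log10(5e-5))
        assert np.isnan(row["log10_s2"])

    def test_missing_total_reads_rejected(self):
        with pytest.raises(ValueError):
            abundance_table({"b1": {"s1": 1.0}}, {})
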
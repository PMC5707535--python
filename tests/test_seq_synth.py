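"""Synthetic-cocktail generator: determinism, bounds, and truth conservation."""

import numpy as np
import pytest

from cocktailscope import seq_synth as ss
from cocktailscope.seq_synth import ParameterError


def brute_tnf(seq: str) -> dict:
    """Independent canonical tetramer counter (plain dict, no numpy)."""
    comp = str.maketrans("ACGT", "TGCA")
    counts: dict[str, int] = {}
    for i in range(len(seq) - 3):
        w = seq[i : i + 4]
        if set(w) - set("ACGT"):
            continue
        rc = w.translate(comp)[::-1]
        counts[min(w, rc)] = counts.get(min(w, rc), 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def tnf_dist(a: dict, b: dict) -> float:
    keys = set(a) | set(b)
    return sum((a.get(k, 0) - b.get(k, 0)) ** 2 for k in keys) ** 0.5


class TestGeneratePhageDb:
    def test_deterministic_given_seed(self):
        a, _ = ss.generate_phage_db(1, (10_000, 12_000), seed=7)
        b, _ = ss.generate_phage_db(1, (10_000, 12_000), seed=7)
        assert a[0].sequence == b[0].sequence

    def test_lengths_within_range_and_count(self):
        db, _ = ss.generate_phage_db(6, (20_000, 60_000), seed=1)
        assert len(db) == 6
        assert all(20_000 <= len(p) <= 60_000 for p in db)
        assert all(set(p.sequence) <= set("ACGT") for p in db)

    def test_host_labels_round_robin(self):
        db, _ = ss.generate_phage_db(5, (10_000, 11_000), n_hosts=2, seed=2)
        assert [p.host_label for p in db] == [
            "Host_sp0", "Host_sp1", "Host_sp0", "Host_sp1", "Host_sp0"
        ]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            ss.generate_phage_db(0, (10_000, 20_000))
        with pytest.raises(ParameterError):
            ss.generate_phage_db(2, (20_000, 10_000))

    def test_compositional_separability_by_direct_counting(self):
        """Between-genome tetramer distance exceeds within-genome window
        distance, verified with an independent brute-force counter."""
        db, _ = ss.generate_phage_db(2, (30_000, 40_000), seed=5)
        within = []
        for p in db:
            wins = [
                brute_tnf(p.sequence[i : i + 5000])
                for i in range(0, len(p) - 5000, 5000)
            ]
            within += [
                tnf_dist(wins[i], wins[j])
                for i in range(len(wins))
                for j in range(i + 1, len(wins))
            ]
        between = tnf_dist(brute_tnf(db[0].sequence), brute_tnf(db[1].sequence))
        assert between > np.mean(within)


class TestDeriveRelative:
    def test_zero_rate_is_identity(self, small_db):
        child = ss.derive_relative(small_db[0], 0.0, seed=1)
        assert child.sequence == small_db[0].sequence
        assert child.parent_id is None and child.divergence == 0.0

    def test_realized_substitution_fraction(self):
        db, _ = ss.generate_phage_db(1, (50_000, 50_000), seed=3)
        child = ss.derive_relative(db[0], 0.05, seed=4)
        mism = sum(a != b for a, b in zip(db[0].sequence, child.sequence))
        assert abs(mism / len(db[0]) - 0.05) < 0.003
        assert child.parent_id == db[0].id and child.divergence == 0.05

    def test_independent_seeds_differ(self, small_db):
        a = ss.derive_relative(small_db[0], 0.05, seed=1)
        b = ss.derive_relative(small_db[0], 0.05, seed=2)
        assert a.sequence != b.sequence

    def test_rates_out_of_range(self, small_db):
        with pytest.raises(ParameterError):
            ss.derive_relative(small_db[0], 0.6)
        with pytest.raises(ParameterError):
            ss.derive_relative(small_db[0], -0.1)


class TestCocktail:
    def test_weights_normalized_and_span_capped(self):
        c = ss.make_cocktail("s", [f"p{i}" for i in range(8)], abundance_span=1000, seed=1)
        w = [wt for _, wt in c.members]
        assert abs(sum(w) - 1.0) < 1e-12
        assert c.abundance_span <= 1000 * (1 + 1e-9)

    def test_span_violation_rejected(self):
        with pytest.raises(ParameterError):
            ss.CocktailSample("s", [("a", 1.0), ("b", 2000.0)], abundance_cap=1000)


class TestSimulateReads:
    def test_empty_is_valid(self, small_db):
        sample = ss.make_cocktail("s", [small_db[0].id], seed=0)
        r1, r2, truth = ss.simulate_reads(sample, small_db, 0, seed=0)
        assert r1 == [] and r2 == [] and truth.read_origin == {}

    def test_deterministic(self, small_db):
        sample = ss.make_cocktail("s", [p.id for p in small_db], seed=0)
        a = ss.simulate_reads(sample, small_db, 200, seed=5)
        b = ss.simulate_reads(sample, small_db, 200, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_equal_weight_read_share(self):
        db, _ = ss.generate_phage_db(2, (30_000, 30_000), seed=9)
        sample = ss.CocktailSample("s", [(db[0].id, 1.0), (db[1].id, 1.0)])
        _, _, truth = ss.simulate_reads(sample, db, 10_000, seed=6)
        share = sum(1 for v in truth.read_origin.values() if v == db[0].id) / 10_000
        assert abs(share - 0.5) < 0.02

    def test_spike_fraction(self, small_db, rng):
        sample = ss.make_cocktail("s", [p.id for p in small_db], seed=0)
        spike = "".join(rng.choice(list("ACGT"), 5000))
        _, _, truth = ss.simulate_reads(
            sample, small_db, 10_000, spike_fraction=0.02, spike_genome=spike, seed=8
        )
        n_spike = sum(1 for v in truth.read_origin.values() if v == "spike")
        assert abs(n_spike - 200) <= 45

    def test_truth_accounts_for_every_read(self, small_db):
        sample = ss.make_cocktail("s", [p.id for p in small_db], seed=0)
        r1, r2, truth = ss.simulate_reads(sample, small_db, 500, seed=2)
        base_ids = {rid[:-2] for rid, _, _ in r1} | {rid[:-2] for rid, _, _ in r2}
        assert base_ids == set(truth.read_origin)


class TestFragmentToContigs:
    def test_full_cover_single_fragment(self, small_db):
        g = small_db[0]
        sample = ss.CocktailSample("s", [(g.id, 1.0)])
        L = len(g)
        contigs, truth = ss.fragment_to_contigs(sample, small_db, (L, L), dropout=0.0, seed=0)
        assert len(contigs) == 1 and contigs[0][1] == g.sequence
        assert truth.contig_origin[contigs[0][0]] == (g.id, 0, L)

    def test_dropout_arithmetic(self):
        db, _ = ss.generate_phage_db(1, (40_000, 40_000), seed=13)
        sample = ss.CocktailSample("s", [(db[0].id, 1.0)])
        contigs, _ = ss.fragment_to_contigs(sample, db, (2_000, 10_000), dropout=0.1, seed=3)
        total = sum(len(seq) for _, seq in contigs)
        assert abs(total - 36_000) <= 10_000  # within one max fragment length

    def test_contigs_are_substrings_with_correct_coordinates(self, small_db):
        sample = ss.make_cocktail("s", [p.id for p in small_db], seed=0)
        contigs, truth = ss.fragment_to_contigs(sample, small_db, (2_000, 8_000), 0.1, seed=4)
        genomes = {p.id: p.sequence for p in small_db}
        assert set(truth.contig_origin) == {cid for cid, _ in contigs}
        for cid, seq in contigs:
            pid, start, end = truth.contig_origin[cid]
            assert genomes[pid][start:end] == seq

    def test_short_fragments_flagged_below_binning_threshold(self, small_db):
        g = small_db[0]
        sample = ss.CocktailSample("s", [(g.id, 1.0)])
        contigs, truth = ss.fragment_to_contigs(sample, small_db, (1_500, 1_500), 0.0, seed=0)
        short = {cid for cid, seq in contigs if len(seq) < 2_000}
        assert short and short == truth.below_min_contigs
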
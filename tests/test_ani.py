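"""ANI engine: local alignment, integrated ANI, reciprocal ANI, host calls."""

import numpy as np
import pytest

from cocktailscope import seq_synth as ss
from cocktailscope._align import SubjectIndex, search, sw_local
from cocktailscope._seq import encode, revcomp
from cocktailscope.ani import (
    AlignmentHit,
    ani_score,
    ani_to_db,
    best_reference,
    find_hits,
    is_phage,
    predict_host,
    read_tabular_hits,
    reciprocal_ani,
    weighted_bin_ani,
    write_tabular_hits,
)
from .conftest import random_dna


def oracle_local_score(a: str, b: str) -> float:
    """Independent optimal local-alignment score (Biopython DP)."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=2,
        mismatch_score=-3,
        open_gap_score=-7,
        extend_gap_score=-2,
    )
    return max(aligner.score(a, b), aligner.score(a, revcomp(b)))


class TestFindHits:
    def test_self_hit_full_length_identity(self):
        db, _ = ss.generate_phage_db(1, (10_000, 10_000), seed=31)
        seq = db[0].sequence
        hits = find_hits(("q", seq), [("s", seq)])
        top = hits[0]
        assert top.identity == 100.0
        assert (top.q_start, top.q_end) == (1, len(seq))

    @pytest.mark.parametrize("pair_seed", range(10))
    def test_score_equals_exhaustive_dp_oracle(self, pair_seed):
        rng = np.random.default_rng(500 + pair_seed)
        a = random_dna(rng, int(rng.integers(60, 200)))
        b = random_dna(rng, int(rng.integers(60, 200)))
        hits = find_hits(("a", a), [("b", b)], evalue_max=None)
        best = max(h.score for h in hits) if hits else 0.0
        assert best == oracle_local_score(a, b)

    def test_unrelated_sequences_have_no_significant_hit(self):
        for rep in range(20):
            rng = np.random.default_rng(rep)
            a = random_dna(rng, 5_000)
            b = random_dna(rng, 5_000)
            assert find_hits(("a", a), [("b", b)], evalue_max=0.05) == []

    def test_reverse_strand_hit_reported_in_forward_coordinates(self):
        db, _ = ss.generate_phage_db(1, (12_000, 12_000), seed=33)
        seq = db[0].sequence
        hits = find_hits(("q", revcomp(seq)), [("s", seq)])
        top = hits[0]
        assert (top.q_start, top.q_end) == (1, len(seq))
        assert top.identity == 100.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            find_hits(("q", ""), [("s", "ACGT")])
        with pytest.raises(ValueError):
            SubjectIndex([])


class TestAniScore:
    def test_single_full_length_perfect_hit(self):
        h = AlignmentHit("q", "s", 100.0, 1000, 1, 1000, 1e-10)
        res = ani_score([h], 1000)
        assert res.ani == 100.0 and res.mcov == 1.0

    def test_two_hit_worked_example(self):
        hits = [
            AlignmentHit("q", "s", 90.0, 1000, 1, 1000, 1e-10),
            AlignmentHit("q", "s", 80.0, 3000, 2001, 5000, 1e-10),
        ]
        res = ani_score(hits, 10_000)
        assert res.mcov == pytest.approx(0.4)
        assert res.ani == pytest.approx(33.0)

    def test_duplicate_hits_do_not_change_coverage_union(self):
        h = AlignmentHit("q", "s", 90.0, 1000, 1, 1000, 1e-10)
        once = ani_score([h], 2000)
        twice = ani_score([h, h], 2000)
        assert twice.mcov == once.mcov
        assert twice.ani == pytest.approx(once.ani)

    def test_empty_hit_list_scores_zero(self):
        res = ani_score([], 5_000)
        assert res.ani == 0.0 and res.mcov == 0.0 and res.n_hits == 0

    def test_interval_outside_query_rejected(self):
        h = AlignmentHit("q", "s", 90.0, 1000, 1, 1001, 1e-10)
        with pytest.raises(ValueError):
            ani_score([h], 1000)

    def test_bounds_hold_for_random_hit_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            qlen = int(rng.integers(1_000, 20_000))
            hits = []
            for _ in range(int(rng.integers(1, 8))):
                start = int(rng.integers(1, qlen - 10))
                end = int(rng.integers(start, qlen) + 1)
                hits.append(
                    AlignmentHit("q", "s", float(rng.uniform(20, 100)),
                                 end - start + 1, start, end, 1e-3)
                )
            res = ani_score(hits, qlen)
            wid = sum(h.identity * h.align_len for h in hits) / sum(
                h.align_len for h in hits
            )
            assert 0.0 <= res.ani <= 100.0
            assert res.ani <= wid + 1e-9
            assert res.ani <= 100.0 * res.mcov + 1e-9


class TestWeightedBinAni:
    def test_single_contig_identity(self):
        assert weighted_bin_ani([(97.37, 72_136)]) == pytest.approx(97.37)

    def test_two_contig_worked_example(self):
        assert weighted_bin_ani([(40.0, 1000), (80.0, 3000)]) == pytest.approx(70.0)

    def test_equal_lengths_reduce_to_arithmetic_mean(self):
        assert weighted_bin_ani([(60.0, 500), (90.0, 500)]) == pytest.approx(75.0)

    def test_empty_or_degenerate_rejected(self):
        with pytest.raises(ValueError):
            weighted_bin_ani([])
        with pytest.raises(ValueError):
            weighted_bin_ani([(50.0, 0)])


class TestBestReferenceAndPhageCall:
    def test_identical_reference_ranks_first(self, small_db):
        g = small_db[0]
        refdb = [(p.id, p.sequence) for p in small_db]
        ranked = best_reference([("c0", g.sequence)], refdb)
        assert ranked[0][0] == g.id
        assert ranked[0][1] > 99.0

    def test_mutated_parent_recovered_over_decoy(self, small_db):
        parent = small_db[0]
        child = ss.derive_relative(parent, 0.05, seed=41)
        refdb = [(p.id, p.sequence) for p in small_db]
        half = len(child.sequence) // 2
        bin_seqs = [("c0", child.sequence[:half]), ("c1", child.sequence[half:])]
        ranked = best_reference(bin_seqs, refdb)
        assert ranked[0][0] == parent.id

    def test_phage_call_threshold_is_inclusive(self, small_db):
        g = small_db[1]
        refdb = [(p.id, p.sequence) for p in small_db]
        bin_seqs = [("c0", g.sequence)]
        observed = ani_to_db(bin_seqs, refdb).ani
        assert is_phage(bin_seqs, refdb, threshold=observed)  # >= not >

    def test_unrelated_bin_is_not_phage(self, small_db, rng):
        refdb = [(p.id, p.sequence) for p in small_db]
        assert not is_phage([("c0", random_dna(rng, 15_000))], refdb)

    def test_ani_monotone_in_divergence(self):
        db, _ = ss.generate_phage_db(1, (30_000, 30_000), seed=3)
        g = db[0]
        index = SubjectIndex([(g.id, g.sequence)])
        anis = []
        for d in (0.0, 0.02, 0.05, 0.10, 0.20):
            q = g if d == 0 else ss.derive_relative(g, d, seed=9)
            anis.append(ani_to_db([("q", q.sequence)], index).ani)
        assert all(a >= b - 0.5 for a, b in zip(anis, anis[1:]))


class TestReciprocalAni:
    def test_identical_sequences_score_100(self, small_db):
        s = [("a", small_db[0].sequence)]
        assert reciprocal_ani(s, [("b", small_db[0].sequence)]) == pytest.approx(100.0)

    def test_two_percent_divergence_recovered(self):
        db, _ = ss.generate_phage_db(1, (35_000, 35_000), seed=3)
        g = db[0]
        m = ss.derive_relative(g, 0.02, seed=4)
        mism = sum(a != b for a, b in zip(g.sequence, m.sequence)) / len(g)
        r = reciprocal_ani([("a", g.sequence)], [("b", m.sequence)])
        assert r == pytest.approx(100.0 * (1 - mism), abs=0.5)

    def test_exact_symmetry(self):
        db, _ = ss.generate_phage_db(2, (20_000, 25_000), seed=8)
        m = ss.derive_relative(db[0], 0.05, seed=5)
        a = [(db[0].id, db[0].sequence)]
        b = [("x", m.sequence), ("y", db[1].sequence[:5_000])]
        assert reciprocal_ani(a, b) == reciprocal_ani(b, a)

    def test_short_sequence_uses_truncated_fragment(self):
        db, _ = ss.generate_phage_db(1, (20_000, 20_000), seed=12)
        short = db[0].sequence[:800]
        assert reciprocal_ani(
            [("a", short)], [("b", db[0].sequence)]
        ) == pytest.approx(100.0)


class TestPredictHost:
    def _host_db(self, n_decoys=20, seed=60):
        db, _ = ss.generate_phage_db(n_decoys + 1, (15_000, 25_000), n_hosts=5, seed=seed)
        target = db[0]
        return target, [(p.id, p.sequence, p.host_label) for p in db]

    def test_identical_bin_recovers_host_with_high_score(self):
        target, host_db = self._host_db()
        pred = predict_host([("c0", target.sequence)], host_db)
        assert pred.host == target.host_label
        assert pred.score > 0.9 and pred.reliable

    def test_no_shared_kmers_is_unreliable(self, rng):
        _, host_db = self._host_db()
        pred = predict_host([("c0", random_dna(rng, 10_000))], host_db)
        assert pred.score == 0.0 and not pred.reliable and pred.host is None

    def test_diverged_bin_recovers_host_across_replicates(self):
        target, host_db = self._host_db()
        cache: dict = {}
        wins = 0
        for rep in range(50):
            child = ss.derive_relative(target, 0.05, seed=1000 + rep)
            pred = predict_host([("c0", child.sequence)], host_db, _db_cache=cache)
            wins += pred.host == target.host_label
        assert wins >= 48  # >= 95% of 50 seeded replicates


class TestTabularHits:
    def test_round_trip(self, tmp_path):
        hits = [
            AlignmentHit("q", "s", 97.5, 1234, 10, 1243, 1e-20, 5, 1238, 2000.0),
            AlignmentHit("q", "t", 88.0, 400, 50, 449, 1e-5, 1, 400, 300.0),
        ]
        p = tmp_path / "hits.tsv"
        write_tabular_hits(p, hits)
        back = read_tabular_hits(p)
        assert [(h.subject_id, h.align_len, h.q_start) for h in back] == [
            ("s", 1234, 10), ("t", 400, 50)
        ]
        assert ani_score(back, 2_000).n_hits == 2
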
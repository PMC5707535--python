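"""Ground-truth recovery experiments for the whole pipeline.

Each function builds a synthetic scenario with known truth, runs the
relevant pipeline stage(s), and returns the measured recovery quantities.
They are the package's self-validation suite: the same experiments back the
acceptance script and the heavier end of the test suite.

Problem sizes are chosen so the full battery runs in minutes on one core:
genomes of 20-60 kb, cocktails of up to 8 members, up to 100k read pairs
for the abundance experiment and three 50k-pair read sets for the sketch
experiment.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import seq_synth as ss
from .ani import ani_score, best_reference, find_hits, weighted_bin_ani
from .binning import Bin, Contig, bin_contigs
from .curation import CoverageProfile, classify, depth_profile, merge_bins, pair_bins, split_bin
from .sketch import bootstrap_distances


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1_000 + offset) % (2**31)


def alignment_engine_check(seed: int = 0, n_pairs: int = 50) -> dict:
    """Hit scores vs an exhaustive local-alignment oracle, plus the two
    closed-form ANI examples.

    On ``n_pairs`` random sequence pairs up to 200 bp the package's best hit
    score is compared with Biopython's optimal local-alignment score under
    the same scoring scheme; the returned ``score_agreement`` is the
    fraction of pairs in exact agreement.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local", match_score=2, mismatch_score=-3,
        open_gap_score=-7, extend_gap_score=-2,
    )
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        a = "".join(rng.choice(list("ACGT"), int(rng.integers(50, 201))))
        b = "".join(rng.choice(list("ACGT"), int(rng.integers(50, 201))))
        hits = find_hits(("a", a), [("b", b)], evalue_max=None)
        mine = max((h.score for h in hits), default=0.0)
        from cocktailscope._seq import revcomp

        oracle = max(aligner.score(a, b), aligner.score(a, revcomp(b)))
        agree += mine == oracle
    from .ani import AlignmentHit

    two_hit = ani_score(
        [
            AlignmentHit("q", "s", 90.0, 1000, 1, 1000, 1e-10),
            AlignmentHit("q", "s", 80.0, 3000, 2001, 5000, 1e-10),
        ],
        10_000,
    ).ani
    return {
        "score_agreement": agree / n_pairs,
        "ani_two_hit_example": two_hit,
        "weighted_bin_ani_example": weighted_bin_ani([(40.0, 1000), (80.0, 3000)]),
    }


def binning_recovery(seed: int = 0) -> dict:
    """Six genomes, 2-10 kb fragments, 10% dropout: contig purity and the
    fraction of eligible basepairs that end up binned."""
    db, _ = ss.generate_phage_db(6, (20_000, 60_000), seed=_sub_seed(seed, 1))
    sample = ss.make_cocktail("s", [p.id for p in db], seed=_sub_seed(seed, 2))
    raw, truth = ss.fragment_to_contigs(
        sample, db, (2_000, 10_000), dropout=0.1, seed=_sub_seed(seed, 3)
    )
    contigs = [Contig(cid, seq) for cid, seq in raw]
    bins, _unbinned = bin_contigs(contigs)
    pure = 0
    total = 0
    for b in bins:
        origins = [truth.contig_origin[c][0] for c in b.contig_ids]
        majority = max(set(origins), key=origins.count)
        pure += sum(1 for o in origins if o == majority)
        total += len(origins)
    eligible_bp = sum(c.length for c in contigs if c.length >= 2_000)
    binned_bp = sum(b.total_bp for b in bins)
    return {
        "contig_purity": pure / total if total else 0.0,
        "binned_bp_fraction": binned_bp / eligible_bp,
        "n_bins": len(bins),
    }


def _engineered_curation_case(seed: int) -> tuple[list[Bin], CoverageProfile, dict, dict]:
    """One engineered split/merge scenario.

    Genomes 0 and 1 are co-binned with a >= 1.3 depth ratio (must split);
    genome 2 is spread over three same-depth fragment bins (must merge).
    Returns (bins, profile, contig_seqs, truth_labels).
    """
    db, _ = ss.generate_phage_db(3, (30_000, 45_000), seed=seed)
    rng = np.random.default_rng(seed + 1)
    contig_seqs: dict[str, str] = {}
    depth: dict[str, float] = {}
    labels: dict[str, str] = {}
    base_depth = {db[0].id: 10.0, db[1].id: 13.5, db[2].id: 20.0}  # 1.35 ratio
    frags: dict[str, list[str]] = {p.id: [] for p in db}
    for p in db:
        pos = 0
        i = 0
        while pos < len(p):
            fl = int(rng.integers(4_000, 8_000))
            seq = p.sequence[pos : pos + fl]
            if len(seq) >= 2_000:
                cid = f"{p.id}_c{i}"
                contig_seqs[cid] = seq
                depth[cid] = base_depth[p.id] * float(rng.uniform(0.97, 1.03))
                labels[cid] = p.id
                frags[p.id].append(cid)
                i += 1
            pos += fl
    mixed = sorted(frags[db[0].id] + frags[db[1].id])
    thirds = frags[db[2].id]
    cut = max(1, len(thirds) // 3)
    bins = [Bin("bin_1", mixed, sum(len(contig_seqs[c]) for c in mixed))]
    for j, part in enumerate((thirds[:cut], thirds[cut : 2 * cut], thirds[2 * cut :])):
        if part:
            bins.append(
                Bin(f"bin_{j + 2}", sorted(part), sum(len(contig_seqs[c]) for c in part))
            )
    profile = CoverageProfile(
        contig_mean=depth,
        contig_sd={c: 0.0 for c in depth},
        contig_len={c: len(s) for c, s in contig_seqs.items()},
    )
    return bins, profile, contig_seqs, labels


def split_merge_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Adjusted Rand index of split+merge curation against the true
    genome-of-origin partition, over ``n_seeds`` engineered scenarios."""
    aris = []
    for i in range(n_seeds):
        case_seed = _sub_seed(seed, 10 + i)
        bins, profile, contig_seqs, labels = _engineered_curation_case(case_seed)
        db, _ = ss.generate_phage_db(3, (30_000, 45_000), seed=case_seed)
        refdb = [(f"ref_{p.id}", p.sequence) for p in db]
        split = [sb for b in bins for sb in split_bin(b, profile)]
        best = {
            b.id: best_reference([(c, contig_seqs[c]) for c in b.contig_ids], refdb)[0][0]
            for b in split
        }
        final = merge_bins(split, best, profile, contig_seqs)
        ids = sorted(contig_seqs)
        truth_part = [labels[c] for c in ids]
        assign = {c: b.id for b in final for c in b.contig_ids}
        pred_part = [assign[c] for c in ids]
        aris.append(adjusted_rand_score(truth_part, pred_part))
    return {"ari_mean": float(np.mean(aris)), "ari_min": float(np.min(aris)), "n_seeds": n_seeds}


def classification_fixture_accuracy() -> dict:
    """Six constructed fixtures, one per category, built on the precedents a
    curated cocktail shows: very low ANI and hopeless fragmentation are
    special cases, oversized bins with internal overlap are collapsed, a
    high-ANI bin much shorter than its reference is still partial."""
    ref_len = 100_000
    fixtures = [
        (dict(bin_length=96_000, contig_lengths=[96_000], ref_ani=96.86,
              ref_len=ref_len, has_counterpart=True), 1),
        (dict(bin_length=96_000, contig_lengths=[96_000], ref_ani=96.86,
              ref_len=ref_len, has_counterpart=False), 2),
        (dict(bin_length=40_000, contig_lengths=[40_000], ref_ani=22.1,
              ref_len=ref_len, has_counterpart=True), 3),
        (dict(bin_length=80_000, contig_lengths=[80_000], ref_ani=75.0,
              ref_len=ref_len, has_counterpart=False), 4),
        (dict(bin_length=115_000, contig_lengths=[60_000, 55_000], ref_ani=90.0,
              ref_len=ref_len, has_counterpart=False, has_internal_overlap=True), 5),
        (dict(bin_length=11_313, contig_lengths=[11_313], ref_ani=0.704,
              ref_len=ref_len, has_counterpart=False), 6),
        (dict(bin_length=78_000, contig_lengths=[3_000] * 26, ref_ani=42.11,
              ref_len=ref_len, has_counterpart=True), 6),
    ]
    correct = sum(classify(**kw) == want for kw, want in fixtures)
    return {"classification_accuracy": correct / len(fixtures), "n_fixtures": len(fixtures)}


def pairing_recovery(seed: int = 0, divergence: float = 0.02) -> dict:
    """Two 8-member cocktails sharing 5 genomes (the shared members carry a
    controlled between-batch divergence): number of cross-sample matches and
    the worst reciprocal-ANI error against 100*(1 - divergence)."""
    db, _ = ss.generate_phage_db(11, (20_000, 40_000), seed=_sub_seed(seed, 20))
    shared = db[:5]
    only_a = db[5:8]
    only_b = db[8:11]
    shared_b = [
        ss.derive_relative(p, divergence, seed=_sub_seed(seed, 30 + i), child_id=f"{p.id}_b")
        for i, p in enumerate(shared)
    ]

    def bins_for(members, tag, fseed):
        sample = ss.make_cocktail(tag, [p.id for p in members], seed=fseed)
        raw, truth = ss.fragment_to_contigs(
            sample, members, (2_000, 10_000), dropout=0.1, seed=fseed
        )
        out: dict[str, list[tuple[str, str]]] = {}
        for cid, seq in raw:
            if len(seq) < 2_000:
                continue
            pid = truth.contig_origin[cid][0]
            out.setdefault(pid, []).append((cid, seq))
        return out

    bins_a = bins_for(shared + only_a, "A", _sub_seed(seed, 21))
    bins_b = bins_for(shared_b + only_b, "B", _sub_seed(seed, 22))
    matches = pair_bins(bins_a, bins_b)
    expected = {(p.id, f"{p.id}_b") for p in shared}
    got = {(m.bin_a, m.bin_b) for m in matches}
    realized = {}
    for p, pb in zip(shared, shared_b):
        mism = sum(a != b for a, b in zip(p.sequence, pb.sequence)) / len(p)
        realized[p.id] = 100.0 * (1 - mism)
    errors = [
        abs(m.reciprocal_ani - realized[m.bin_a]) for m in matches if m.bin_a in realized
    ]
    return {
        "n_matches": len(matches),
        "n_expected": len(expected),
        "match_set_correct": got == expected,
        "reciprocal_ani_max_error": float(max(errors)) if errors else float("nan"),
    }


def abundance_recovery(seed: int = 0, n_pairs: int = 100_000) -> dict:
    """Pearson correlation between log10 normalized coverage and log10 true
    weight over a 1000-fold abundance span."""
    db, _ = ss.generate_phage_db(8, (20_000, 40_000), seed=_sub_seed(seed, 40))
    sample = ss.make_cocktail("s", [p.id for p in db], abundance_span=1000.0,
                              seed=_sub_seed(seed, 41))
    r1, r2, _ = ss.simulate_reads(sample, db, n_pairs, error_rate=0.01,
                                  seed=_sub_seed(seed, 42))
    contigs = [(p.id, p.sequence) for p in db]
    profile = depth_profile(contigs, reads=(r1, r2), seed=_sub_seed(seed, 43),
                            keep_arrays=False)
    weights = sample.weights()
    logw, logc = [], []
    for pid, w in weights.items():
        norm = profile.contig_mean[pid] / (2 * n_pairs)
        if norm > 0:
            logw.append(math.log10(w))
            logc.append(math.log10(norm))
    r = float(np.corrcoef(logw, logc)[0, 1])
    return {"abundance_log_pearson_r": r, "n_genomes_detected": len(logc)}


def sketch_recovery(seed: int = 0, rates=(0.01, 0.05, 0.1), n_pairs: int = 800) -> dict:
    """Mutation-distance recovery: |D - d| against 3x the bootstrap SD
    (hash-seed-varying bootstrap, which is variance-complete)."""
    out = {}
    for d in rates:
        db, _ = ss.generate_phage_db(1, (40_000, 40_000), seed=_sub_seed(seed, 50))
        g = db[0]
        m = ss.derive_relative(g, d, seed=_sub_seed(seed, 51 + int(d * 100)))
        reads = {}
        for name, phage, s_off in (("a", g, 60), ("b", m, 61)):
            sample = ss.CocktailSample(name, [(phage.id, 1.0)])
            r1, r2, _ = ss.simulate_reads(sample, [phage], n_pairs, error_rate=0.005,
                                          seed=_sub_seed(seed, s_off + int(d * 1000)))
            reads[name] = [x[1] for x in r1 + r2]
        est, _ = bootstrap_distances(reads, reps=100, seed=_sub_seed(seed, 70),
                                     vary_hash=True)
        e = est[("a", "b")]
        out[f"distance_at_{d}"] = e.d
        out[f"distance_error_at_{d}"] = abs(e.d - d)
        out[f"bootstrap_sd_at_{d}"] = e.bootstrap_sd
        out[f"within_3sd_at_{d}"] = bool(abs(e.d - d) <= 3 * e.bootstrap_sd)
    return out


def sketch_cocktail_ordering(
    seed: int = 0, n_pairs: int = 50_000, abundance_span: float = 20.0
) -> dict:
    """Three 50k-pair cocktail read sets through the full 100-replicate
    bootstrap: a third sample built from sample A's genomes must sit closer
    to A than to B (the older-batch comparison logic).

    The abundance span is kept at 20-fold here: at this scaled-down read
    budget a wider span pushes the rarest members below the sketch's
    2-copy multiplicity floor, and membership differences — the quantity
    the distance is meant to rank — would drown in abundance-dropout noise
    that the full-size data does not exhibit.
    """
    db, _ = ss.generate_phage_db(10, (20_000, 40_000), seed=_sub_seed(seed, 80))
    ids = [p.id for p in db]
    sample_a = ss.make_cocktail("A", ids[:7], abundance_span, seed=_sub_seed(seed, 81))
    sample_b = ss.make_cocktail("B", ids[3:10], abundance_span, seed=_sub_seed(seed, 82))
    # C re-mixes A's genome set with its own abundance draw
    sample_c = ss.make_cocktail("C", ids[:7], abundance_span, seed=_sub_seed(seed, 83))
    reads = {}
    for sample, off in ((sample_a, 84), (sample_b, 85), (sample_c, 86)):
        r1, r2, _ = ss.simulate_reads(sample, db, n_pairs, error_rate=0.01,
                                      seed=_sub_seed(seed, off))
        reads[sample.id] = [x[1] for x in r1 + r2]
    est, tables = bootstrap_distances(reads, reps=100, seed=_sub_seed(seed, 87))
    d_ca = est[("A", "C")].d
    d_cb = est[("B", "C")].d
    return {
        "n_bootstrap_tables": len(tables),
        "d_third_to_a": d_ca,
        "d_third_to_b": d_cb,
        "ordering_holds": bool(d_ca < d_cb),
        "d_a_b": est[("A", "B")].d,
        "se_a_b": est[("A", "B")].bootstrap_se,
    }
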
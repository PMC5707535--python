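"""Coverage profiles, bin curation (split/merge), cross-sample pairing,
six-way classification, and the abundance comparison.

Coverage is mean per-base read depth per contig. Mixed bins are detected by
a high coefficient of variation of member-contig depths and split at the
largest gap in sorted depth; bins that share a best reference, have similar
depth and no overlapping contigs are merged — the rationale being that one
phage genome fragmented across bins shows one depth, while two phages
co-binned by composition usually differ in depth.

Final bins fall into six categories:
  1 near-complete, high (>= 70%) reference ANI, counterpart in other sample
  2 near-complete, high reference ANI, no counterpart
  3 partial or low/medium reference ANI, counterpart present
  4 partial or low/medium reference ANI, no counterpart
  5 collapsed: > 10% longer than the reference with internally overlapping
    contigs (co-assembled close relatives)
  6 special case: < 10% ANI to any known phage, or hopelessly fragmented
    (> 20 contigs, all < 7000 bp)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import SubjectIndex, search
from ._seq import encode, kmer_codes, revcomp
from .ani import ani_to_db, reciprocal_ani
from .binning import Bin

CATEGORY_LABELS = {
    1: "Near-complete draft genome with high resemblance to reference phage "
       "and counterpart in the other sample.",
    2: "Near-complete draft genome with high resemblance to reference phage, "
       "but no counterpart in the other sample.",
    3: "Partial draft genome with low/medium resemblance to reference phage "
       "and counterpart in the other sample.",
    4: "Partial draft genome with no resemblance to reference phage and no "
       "counterpart in the other sample.",
    5: "Collapsed bins.",
    6: "Special cases, including highly fragmented bins and bins classified "
       "as non-phages.",
}

MIN_BIN_BP = 10_000
FRAGMENTED_MAX_CONTIG = 7_000
FRAGMENTED_MIN_CONTIGS = 20
OVERLAP_MIN_LEN = 500
OVERLAP_MIN_IDENTITY = 95.0


class FormatError(ValueError):
    pass


@dataclass
class CoverageProfile:
    """Per-contig mean depth +/- sd, with per-base arrays retained."""

    contig_mean: dict[str, float]
    contig_sd: dict[str, float]
    contig_len: dict[str, int]
    n_mapped: int = 0
    depth_arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def bin_mean(self, contig_ids: list[str]) -> float:
        """Length-weighted mean depth of a set of contigs."""
        num = sum(self.contig_mean[c] * self.contig_len[c] for c in contig_ids)
        den = sum(self.contig_len[c] for c in contig_ids)
        return num / den if den else 0.0

    def bin_sd(self, contig_ids: list[str]) -> float:
        if not self.depth_arrays:
            return float("nan")
        d = np.concatenate([self.depth_arrays[c] for c in contig_ids])
        return float(d.std())


@dataclass
class BinMatch:
    bin_a: str
    bin_b: str
    ani_a_to_b: float  # a's contigs queried against b as database
    ani_b_to_a: float
    reciprocal_ani: float = float("nan")


class ReadMapper:
    """Word-seeded best-placement read mapper over a contig set.

    Seeds (31-mers at a stride across the read, both strands) nominate
    candidate diagonals; the read is compared base-wise at each candidate
    placement and the highest-identity placement wins, provided identity is
    at least ``min_identity`` over the aligned span. Ties are broken by a
    seeded RNG so depth profiles are reproducible.
    """

    def __init__(self, contigs: list[tuple[str, str]], word: int = 31,
                 min_identity: float = 0.9, seed: int = 0):
        if not contigs:
            raise ValueError("empty contig set")
        self.word = word
        self.min_identity = min_identity
        self.ids = [cid for cid, _ in contigs]
        self.codes = [encode(seq) for _, seq in contigs]
        self.rng = np.random.default_rng(seed)
        km_all, subj_all, pos_all = [], [], []
        for si, codes in enumerate(self.codes):
            km, valid = kmer_codes(codes, word)
            idx = np.flatnonzero(valid)
            km_all.append(km[idx])
            subj_all.append(np.full(len(idx), si, dtype=np.int64))
            pos_all.append(idx.astype(np.int64))
        km = np.concatenate(km_all)
        order = np.argsort(km, kind="stable")
        self._kmers = km[order]
        self._subj = np.concatenate(subj_all)[order]
        self._pos = np.concatenate(pos_all)[order]

    def place(self, seq: str) -> tuple[int, int, int] | None:
        """Best placement ``(contig_idx, start, end)`` of a read, or None."""
        best = None
        best_ident = self.min_identity - 1e-9
        ties: list[tuple[int, int, int]] = []
        for strand_seq in (seq, revcomp(seq)):
            codes = encode(strand_seq)
            km, valid = kmer_codes(codes, self.word)
            if len(km) == 0:
                continue
            offsets = range(0, len(km), max(1, self.word // 2))
            seen: set[tuple[int, int]] = set()
            for q in offsets:
                if not valid[q]:
                    continue
                lo = np.searchsorted(self._kmers, km[q], side="left")
                hi = np.searchsorted(self._kmers, km[q], side="right")
                for e in range(lo, hi):
                    si, spos = int(self._subj[e]), int(self._pos[e])
                    diag = q - spos
                    if (si, diag) in seen:
                        continue
                    seen.add((si, diag))
                    ctg = self.codes[si]
                    a = max(0, diag)
                    b = min(len(codes), len(ctg) + diag)
                    span = b - a
                    if span < self.word:
                        continue
                    m = codes[a:b] == ctg[a - diag : b - diag]
                    ident = m.sum() / span
                    if ident < self.min_identity:
                        continue
                    placement = (si, a - diag, b - diag)
                    if ident > best_ident + 1e-12:
                        best_ident = ident
                        best = placement
                        ties = [placement]
                    elif abs(ident - best_ident) <= 1e-12:
                        ties.append(placement)
        if best is None:
            return None
        if len(ties) > 1:
            return ties[self.rng.integers(0, len(ties))]
        return best


def depth_profile(
    contigs: list[tuple[str, str]],
    reads: tuple[list, list] | None = None,
    alignments: str | None = None,
    seed: int = 0,
    keep_arrays: bool = True,
) -> CoverageProfile:
    """Per-contig coverage from reads (internal mapper) or a SAM/BAM file.

    With fully aligned reads this equals the reads x read-length / contig-
    length formula.
    """
    if not contigs:
        raise ValueError("empty contig set")
    depths = {cid: np.zeros(len(seq), dtype=np.int32) for cid, seq in contigs}
    ids = [cid for cid, _ in contigs]
    n_mapped = 0
    if alignments is not None:
        n_mapped = _accumulate_sam(alignments, depths)
    elif reads is not None:
        mapper = ReadMapper(contigs, seed=seed)
        for mate in reads:
            for _, seq, _ in mate:
                hit = mapper.place(seq)
                if hit is not None:
                    si, a, b = hit
                    depths[ids[si]][a:b] += 1
                    n_mapped += 1
    profile = CoverageProfile(
        contig_mean={cid: float(d.mean()) for cid, d in depths.items()},
        contig_sd={cid: float(d.std()) for cid, d in depths.items()},
        contig_len={cid: len(seq) for cid, seq in contigs},
        n_mapped=n_mapped,
        depth_arrays=depths if keep_arrays else {},
    )
    return profile


def _accumulate_sam(path: str, depths: dict[str, np.ndarray]) -> int:
    import pysam

    n_mapped = 0
    try:
        fh = pysam.AlignmentFile(path, check_sq=False)
    except ValueError as exc:
        raise FormatError(f"cannot parse alignments: {exc}") from exc
    with fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name not in depths:
                continue
            arr = depths[rec.reference_name]
            for start, end in rec.get_blocks():
                arr[start : min(end, len(arr))] += 1
            n_mapped += 1
    return n_mapped


def _largest_gap_split(ids: list[str], depth: dict[str, float]) -> tuple[list[str], list[str]]:
    ordered = sorted(ids, key=lambda c: (depth[c], c))
    gaps = [depth[ordered[i + 1]] - depth[ordered[i]] for i in range(len(ordered) - 1)]
    cut = int(np.argmax(gaps)) + 1
    return ordered[:cut], ordered[cut:]


def split_bin(
    b: Bin,
    profile: CoverageProfile,
    cv_threshold: float = 0.1,
    min_bin: int = MIN_BIN_BP,
) -> list[Bin]:
    """Split a bin whose member-contig depths are too heterogeneous.

    While the coefficient of variation of member depths exceeds
    ``cv_threshold``, contigs are partitioned at the largest gap in sorted
    depth, recursively. Resulting groups below ``min_bin`` bp are re-attached
    to the sibling group with the nearest mean depth.
    """
    depth = profile.contig_mean

    def recurse(ids: list[str]) -> list[list[str]]:
        if len(ids) < 2:
            return [ids]
        d = np.array([depth[c] for c in ids])
        if d.mean() == 0 or d.std() / d.mean() <= cv_threshold:
            return [ids]
        left, right = _largest_gap_split(ids, depth)
        return recurse(left) + recurse(right)

    groups = recurse(list(b.contig_ids))
    if len(groups) == 1:
        return [b]
    # re-attach undersized groups to the nearest-depth sibling
    def group_bp(g):
        return sum(profile.contig_len[c] for c in g)

    def group_depth(g):
        return profile.bin_mean(g)

    changed = True
    while changed and len(groups) > 1:
        changed = False
        for g in list(groups):
            if group_bp(g) < min_bin:
                groups.remove(g)
                target = min(groups, key=lambda h: abs(group_depth(h) - group_depth(g)))
                target.extend(g)
                changed = True
                break
    if len(groups) == 1:
        return [Bin(b.id, sorted(groups[0]), group_bp(groups[0]), provenance=b.provenance)]
    groups.sort(key=lambda g: -group_bp(g))
    return [
        Bin(f"{b.id}.{i + 1}", sorted(g), group_bp(g), provenance="split")
        for i, g in enumerate(groups)
    ]


def _has_overlap(
    seqs_a: list[tuple[str, str]],
    seqs_b: list[tuple[str, str]],
    min_len: int = OVERLAP_MIN_LEN,
    min_identity: float = OVERLAP_MIN_IDENTITY,
) -> bool:
    """Any contig-contig local alignment >= min_len at >= min_identity?"""
    index = SubjectIndex(seqs_b)
    for _, seq in seqs_a:
        for h in search(seq, index, evalue_max=0.05):
            if h.align_len >= min_len and h.identity >= min_identity:
                return True
    return False


def internal_overlap(bin_seqs: list[tuple[str, str]]) -> bool:
    """True when two distinct contigs of one bin align to each other."""
    for i, (cid, seq) in enumerate(bin_seqs):
        others = bin_seqs[:i] + bin_seqs[i + 1 :]
        if others and _has_overlap([(cid, seq)], others):
            return True
    return False


def merge_bins(
    bins: list[Bin],
    best_refs: dict[str, str],
    profile: CoverageProfile,
    contig_seqs: dict[str, str],
    cov_tolerance: float = 0.25,
) -> list[Bin]:
    """Merge bins that look like fragments of one genome.

    Two bins qualify when they share the best reference, their mean depths
    agree within ``cov_tolerance`` (relative), and no contig of one aligns
    to a contig of the other (>= 500 bp at >= 95%). Merging is the
    transitive closure over qualifying pairs.
    """
    parent = {b.id: b.id for b in bins}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_id = {b.id: b for b in bins}
    ids = [b.id for b in bins]
    for i, a in enumerate(ids):
        for b_id in ids[i + 1 :]:
            if best_refs.get(a) != best_refs.get(b_id):
                continue
            da = profile.bin_mean(by_id[a].contig_ids)
            db_ = profile.bin_mean(by_id[b_id].contig_ids)
            if max(da, db_) == 0 or abs(da - db_) / max(da, db_) > cov_tolerance:
                continue
            seqs_a = [(c, contig_seqs[c]) for c in by_id[a].contig_ids]
            seqs_b = [(c, contig_seqs[c]) for c in by_id[b_id].contig_ids]
            if _has_overlap(seqs_a, seqs_b):
                continue
            parent[find(a)] = find(b_id)
    groups: dict[str, list[Bin]] = {}
    for b in bins:
        groups.setdefault(find(b.id), []).append(b)
    out = []
    for members in groups.values():
        if len(members) == 1:
            out.append(members[0])
            continue
        members.sort(key=lambda b: -b.total_bp)
        stem = members[0].id
        tails = [m.id.rsplit("_", 1)[-1] for m in members[1:]]
        merged_id = stem + "." + ".".join(tails)
        contig_ids = sorted(c for m in members for c in m.contig_ids)
        out.append(
            Bin(merged_id, contig_ids, sum(m.total_bp for m in members), provenance="merged")
        )
    out.sort(key=lambda b: (-b.total_bp, b.id))
    return out


def pair_bins(
    bins_a: dict[str, list[tuple[str, str]]],
    bins_b: dict[str, list[tuple[str, str]]],
    ani_threshold: float = 70.0,
    compute_reciprocal: bool = True,
) -> list[BinMatch]:
    """Match bins across two samples by weighted ANI.

    For each database bin the best query bin (by length-weighted integrated
    ANI) is the candidate; candidates are kept when the threshold is
    exceeded in at least one direction, and a one-to-one matching is then
    enforced greedily by descending ANI. Swapping the sample labels permutes
    but does not change the match set.
    """
    idx_a = {aid: SubjectIndex(seqs) for aid, seqs in bins_a.items()}
    idx_b = {bid: SubjectIndex(seqs) for bid, seqs in bins_b.items()}
    ani_ab = {}  # (a, b) -> ANI of a's contigs vs b as database
    ani_ba = {}
    for aid, seqs in bins_a.items():
        for bid in bins_b:
            ani_ab[(aid, bid)] = ani_to_db(seqs, idx_b[bid]).ani
    for bid, seqs in bins_b.items():
        for aid in bins_a:
            ani_ba[(aid, bid)] = ani_to_db(seqs, idx_a[aid]).ani
    candidates: set[tuple[str, str]] = set()
    for bid in bins_b:  # b-side bin as database, best a query
        best = max(bins_a, key=lambda a: (ani_ab[(a, bid)], a))
        candidates.add((best, bid))
    for aid in bins_a:
        best = max(bins_b, key=lambda b: (ani_ba[(aid, b)], b))
        candidates.add((aid, best))
    scored = [
        (max(ani_ab[c], ani_ba[c]), c)
        for c in candidates
        if max(ani_ab[c], ani_ba[c]) > ani_threshold
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    matches = []
    for _, (aid, bid) in scored:
        if aid in used_a or bid in used_b:
            continue
        used_a.add(aid)
        used_b.add(bid)
        rani = (
            reciprocal_ani(bins_a[aid], bins_b[bid]) if compute_reciprocal else float("nan")
        )
        matches.append(
            BinMatch(
                bin_a=aid,
                bin_b=bid,
                ani_a_to_b=ani_ab[(aid, bid)],
                ani_b_to_a=ani_ba[(aid, bid)],
                reciprocal_ani=rani,
            )
        )
    return matches


def classify(
    bin_length: int,
    contig_lengths: list[int],
    ref_ani: float,
    ref_len: int,
    has_counterpart: bool,
    has_internal_overlap: bool = False,
    completeness_min: float = 0.9,
    phage_ani_min: float = 10.0,
    high_ani: float = 70.0,
) -> int:
    """Assign one of the six categories (see module docstring).

    Precedence: special case (6) beats collapsed (5) beats the
    completeness/counterpart grid (1-4).
    """
    n_contigs = len(contig_lengths)
    fragmented = n_contigs > FRAGMENTED_MIN_CONTIGS and all(
        l < FRAGMENTED_MAX_CONTIG for l in contig_lengths
    )
    if ref_ani < phage_ani_min or fragmented:
        return 6
    if bin_length > 1.1 * ref_len and has_internal_overlap:
        return 5
    near_complete = bin_length >= completeness_min * ref_len
    if near_complete and ref_ani >= high_ani:
        return 1 if has_counterpart else 2
    return 3 if has_counterpart else 4


def abundance_table(
    bin_depths: dict[str, dict[str, float]],
    total_reads: dict[str, int],
) -> pd.DataFrame:
    """Normalized-coverage table: mean depth / total sample reads.

    ``bin_depths`` maps bin id -> {sample id -> mean depth}. Zero depth is
    reported as missing on the log scale.
    """
    rows = []
    for bin_id, per_sample in sorted(bin_depths.items()):
        row: dict[str, object] = {"bin": bin_id}
        for sample_id, depth in per_sample.items():
            if total_reads.get(sample_id, 0) <= 0:
                raise ValueError(f"total read count missing for sample {sample_id}")
            norm = depth / total_reads[sample_id]
            row[f"normcov_{sample_id}"] = norm
            row[f"log10_{sample_id}"] = np.log10(norm) if norm > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
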
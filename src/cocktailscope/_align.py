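"""Local nucleotide alignment backend.

Two routes share one scoring scheme (match +2, mismatch -3, gap open 5,
gap extend 2 — i.e., a gap of length L costs 5 + 2L):

* exact affine-gap Smith-Waterman with traceback, used when the product of
  sequence lengths is small enough that full dynamic programming is cheap;
* a seed-and-extend route for long sequences: shared 11-mer words define
  candidate diagonals, and on each diagonal the optimal ungapped local
  segment is found exactly (maximum-sum subarray on the +2/-3 profile).

The seeded route is gap-free. Hit significance uses a Karlin-Altschul
e-value with the ungapped lambda for this scoring scheme and K = 0.41,
applied to both routes as an approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._seq import encode, kmer_codes, revcomp

MATCH = 2
MISMATCH = -3
GAP_FIRST = 7  # open(5) + extend(2): cost of the first gapped column
GAP_EXTEND = 2
WORD = 11
KA_K = 0.41
SHORT_CUTOFF = 400_000  # len(q) * total_db_len below which exact DP is used

# ungapped Karlin lambda for +2/-3 at uniform base composition:
# (1/4) e^{2 lambda} + (3/4) e^{-3 lambda} = 1
KA_LAMBDA = float(
    brentq(lambda lam: 0.25 * math.exp(2 * lam) + 0.75 * math.exp(-3 * lam) - 1, 1e-6, 5)
)


def evalue(score: float, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


@dataclass
class RawHit:
    subject_id: str
    score: float
    identity: float  # percent over alignment columns
    align_len: int  # alignment columns, gaps included
    q_start: int  # 1-based inclusive, forward-strand query coordinates
    q_end: int
    s_start: int
    s_end: int
    strand: int  # +1 / -1
    e_value: float


def sw_local(q: np.ndarray, s: np.ndarray) -> tuple[float, int, int, int, int, int, int]:
    """Exact affine-gap Smith-Waterman.

    Returns (score, q_start, q_end, s_start, s_end, matches, aln_columns)
    with 1-based inclusive coordinates of the best local alignment, or score
    0 when no positive-scoring alignment exists.
    """
    n, m = len(q), len(s)
    NEG = -1 << 30
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (move along s)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (move along q)
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # 0 stop, 1 diag, 2 E, 3 F
    eptr = [[0] * (m + 1) for _ in range(n + 1)]  # 1 opened from H, 0 extended
    fptr = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e_open = Hi[j - 1] - GAP_FIRST
            e_ext = Ei[j - 1] - GAP_EXTEND
            if e_open >= e_ext:
                Ei[j] = e_open
                eptr[i][j] = 1
            else:
                Ei[j] = e_ext
            f_open = Hp[j] - GAP_FIRST
            f_ext = Fp[j] - GAP_EXTEND
            if f_open >= f_ext:
                Fi[j] = f_open
                fptr[i][j] = 1
            else:
                Fi[j] = f_ext
            sub = MATCH if qi == s[j - 1] else MISMATCH
            diag = Hp[j - 1] + sub
            h = diag
            p = 1
            if Ei[j] > h:
                h, p = Ei[j], 2
            if Fi[j] > h:
                h, p = Fi[j], 3
            if h <= 0:
                h, p = 0, 0
            Hi[j] = h
            ptr[i][j] = p
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return 0.0, 0, 0, 0, 0, 0, 0
    # traceback
    i, j = bi, bj
    state = 0  # 0 in H, 2 in E, 3 in F
    matches = 0
    cols = 0
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i][j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            cols += 1
            opened = eptr[i][j]
            j -= 1
            if opened:
                state = 0
        else:
            cols += 1
            opened = fptr[i][j]
            i -= 1
            if opened:
                state = 0
    return float(best), i + 1, bi, j + 1, bj, matches, cols


def low_complexity_words(codes: np.ndarray, word: int = WORD) -> np.ndarray:
    """Mask of word-start positions inside low-complexity runs.

    A word is low-complexity when its overlapping 3-mers take at most three
    distinct values — true for homopolymers and repeats of period <= 3,
    false for essentially all random words. Seeding skips such words (the
    same role DUST masking plays for nucleotide BLAST); alignments may still
    extend across repeats from seeds in flanking unique sequence.
    """
    n = len(codes) - word + 1
    if n <= 0:
        return np.empty(0, dtype=bool)
    tri, tri_valid = kmer_codes(codes, 3)
    tri = np.where(tri_valid, tri, -1)
    per_word = word - 2  # 3-mers per word
    windows = np.lib.stride_tricks.sliding_window_view(tri, per_word)[:n]
    sorted_w = np.sort(windows, axis=1)
    distinct = 1 + (np.diff(sorted_w, axis=1) != 0).sum(axis=1)
    return distinct <= 3


class SubjectIndex:
    """Word index over a set of subject sequences for seeded search."""

    def __init__(self, subjects: list[tuple[str, str]], word: int = WORD):
        if not subjects:
            raise ValueError("empty subject set")
        self.word = word
        self.ids = [sid for sid, _ in subjects]
        self.seqs = [seq for _, seq in subjects]
        self.codes = [encode(seq) for seq in self.seqs]
        self.lengths = np.array([len(seq) for seq in self.seqs])
        self.total_len = int(self.lengths.sum())
        km_all, subj_all, pos_all = [], [], []
        for si, codes in enumerate(self.codes):
            km, valid = kmer_codes(codes, word)
            valid = valid & ~low_complexity_words(codes, word)
            idx = np.flatnonzero(valid)
            km_all.append(km[idx])
            subj_all.append(np.full(len(idx), si, dtype=np.int64))
            pos_all.append(idx.astype(np.int64))
        km = np.concatenate(km_all)
        order = np.argsort(km, kind="stable")
        self._kmers = km[order]
        self._subj = np.concatenate(subj_all)[order]
        self._pos = np.concatenate(pos_all)[order]

    def seed_matches(self, q_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(qpos, subject_idx, spos) of every shared word occurrence."""
        km, valid = kmer_codes(q_codes, self.word)
        qpos = np.flatnonzero(valid)
        km = km[qpos]
        left = np.searchsorted(self._kmers, km, side="left")
        right = np.searchsorted(self._kmers, km, side="right")
        counts = right - left
        hitq = np.repeat(qpos, counts)
        # ranges [left, right) flattened
        idx = np.repeat(left, counts) + _ranges_offsets(counts)
        return hitq, self._subj[idx], self._pos[idx]


def _ranges_offsets(counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(c) for each c in counts."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(counts)
    starts = ends - counts
    out = np.arange(total, dtype=np.int64)
    out -= np.repeat(starts, counts)
    return out


def _kadane(vals: np.ndarray) -> tuple[float, int, int]:
    """Best-sum contiguous subarray: (sum, start, end_exclusive)."""
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    mins = np.minimum.accumulate(cs[:-1])
    gains = cs[1:] - mins
    end = int(np.argmax(gains))
    best = float(gains[end])
    start = int(np.argmin(cs[: end + 1]))
    return best, start, end + 1


def _diagonal_hits(
    q_codes: np.ndarray,
    index: SubjectIndex,
    strand: int,
    q_len_fwd: int,
    evalue_max: float | None,
    pad: int = 600,
) -> list[RawHit]:
    hitq, hsubj, hspos = index.seed_matches(q_codes)
    hits: list[RawHit] = []
    if len(hitq) == 0:
        return hits
    qn = len(q_codes)
    diag = hitq - hspos
    key = hsubj * (1 << 32) + (diag + (1 << 24))
    order = np.argsort(key, kind="stable")
    key_s, hq_s = key[order], hitq[order]
    boundaries = np.flatnonzero(np.diff(key_s)) + 1
    group_starts = np.concatenate([[0], boundaries])
    group_ends = np.concatenate([boundaries, [len(key_s)]])
    for gs, ge in zip(group_starts, group_ends):
        si = int(key_s[gs] >> 32)
        d = int((key_s[gs] & 0xFFFFFFFF) - (1 << 24))
        s_codes = index.codes[si]
        sn = len(s_codes)
        q_lo_seed = int(hq_s[gs])
        q_hi_seed = int(hq_s[ge - 1]) + index.word
        q_lo = max(0, q_lo_seed - pad, d)
        q_hi = min(qn, q_hi_seed + pad, sn + d)
        if q_hi <= q_lo:
            continue
        qs = q_codes[q_lo:q_hi]
        ss = s_codes[q_lo - d : q_hi - d]
        match = (qs == ss) & (qs < 4)
        vals = np.where(match, float(MATCH), float(MISMATCH))
        score, a, b = _kadane(vals)
        if score <= 0:
            continue
        ev = evalue(score, q_len_fwd, index.total_len)
        if evalue_max is not None and ev > evalue_max:
            continue
        n_match = int(match[a:b].sum())
        aln_len = b - a
        q_start0, q_end0 = q_lo + a, q_lo + b  # [start, end) on search strand
        s_start0, s_end0 = q_start0 - d, q_end0 - d
        if strand > 0:
            qs1, qe1 = q_start0 + 1, q_end0
        else:  # map back to forward-strand query coordinates
            qs1, qe1 = q_len_fwd - q_end0 + 1, q_len_fwd - q_start0
        hits.append(
            RawHit(
                subject_id=index.ids[si],
                score=score,
                identity=100.0 * n_match / aln_len,
                align_len=aln_len,
                q_start=qs1,
                q_end=qe1,
                s_start=s_start0 + 1,
                s_end=s_end0,
                strand=strand,
                e_value=ev,
            )
        )
    return hits


def _exact_hits(
    query: str, index: SubjectIndex, evalue_max: float | None
) -> list[RawHit]:
    hits: list[RawHit] = []
    qlen = len(query)
    for strand, qseq in ((1, query), (-1, revcomp(query))):
        qc = encode(qseq)
        for si, s_codes in enumerate(index.codes):
            score, qa, qb, sa, sb, matches, cols = sw_local(qc, s_codes)
            if score <= 0 or cols == 0:
                continue
            ev = evalue(score, qlen, index.total_len)
            if evalue_max is not None and ev > evalue_max:
                continue
            if strand > 0:
                qs1, qe1 = qa, qb
            else:
                qs1, qe1 = qlen - qb + 1, qlen - qa + 1
            hits.append(
                RawHit(
                    subject_id=index.ids[si],
                    score=score,
                    identity=100.0 * matches / cols,
                    align_len=cols,
                    q_start=qs1,
                    q_end=qe1,
                    s_start=sa,
                    s_end=sb,
                    strand=strand,
                    e_value=ev,
                )
            )
    return hits


def search(
    query: str, index: SubjectIndex, evalue_max: float | None = 0.05
) -> list[RawHit]:
    """All local-alignment hits of ``query`` against the indexed subjects.

    Chooses the exact DP route for small problems, the seeded diagonal route
    otherwise; hits are sorted by descending score then subject id.
    """
    if len(query) < 1:
        raise ValueError("empty query")
    if len(query) * index.total_len <= SHORT_CUTOFF:
        hits = _exact_hits(query, index, evalue_max)
    else:
        qc_f = encode(query)
        qc_r = encode(revcomp(query))
        hits = _diagonal_hits(qc_f, index, 1, len(query), evalue_max)
        hits += _diagonal_hits(qc_r, index, -1, len(query), evalue_max)
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.q_start))
    return hits
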
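"""Integrated average-nucleotide-identity scoring and annotation.

The central statistic is an ANI that integrates every qualifying local-
alignment hit of a query sequence against a database:

    %ANI = (sum_i id_i * al_i / sum_i al_i) * mcov

where id_i and al_i are each hit's percent identity and alignment length
(e-value <= 0.05 by default) and mcov is the fraction of the query covered
by the union of hit intervals. A query resembling a database entry over its
whole length scores near 100; a query with one short, even perfect, hit is
down-weighted by mcov. For multi-contig bins the per-contig ANIs are
combined length-weighted:

    ANI_bin = sum_i ANI_i * l_i / sum_i l_i

A bin with ANI >= 10 toward a phage reference set is called a phage — a
deliberately stringent cut. Cross-sample comparisons use an orthologous-
fragment reciprocal ANI (both sequences cut into 1020-bp fragments, mean
identity over reciprocal best-hit pairs). Host prediction follows the
shared-16-mer idea: the predicted host is the most represented host among
the database phages sharing the most distinct canonical 16-mers with the
bin, with predictions scoring <= 0.1 flagged unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _align
from ._align import SubjectIndex, search
from ._seq import canonical_kmers, encode

DEFAULT_EVALUE = 0.05
PHAGE_ANI_THRESHOLD = 10.0
ORTHO_FRAG_LEN = 1020
HOST_KMER = 16
HOST_TOP_HITS = 10
HOST_RELIABLE_SCORE = 0.1


@dataclass
class AlignmentHit:
    """One local-alignment hit feeding the integrated ANI."""

    query_id: str
    subject_id: str
    identity: float  # percent
    align_len: int  # bp (alignment columns)
    q_start: int  # 1-based inclusive on the query's forward strand
    q_end: int
    e_value: float
    s_start: int = 0
    s_end: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be a percentage")
        if self.q_start > self.q_end:
            raise ValueError("query interval must be ascending")


@dataclass
class ANIResult:
    ani: float
    mcov: float
    n_hits: int
    per_contig: list[tuple[float, int]] = field(default_factory=list)


@dataclass
class HostPrediction:
    host: str | None
    score: float
    reliable: bool
    top_hits: list[tuple[str, float]] = field(default_factory=list)


def find_hits(
    query: tuple[str, str] | str,
    subjects: list[tuple[str, str]] | SubjectIndex,
    evalue_max: float | None = DEFAULT_EVALUE,
) -> list[AlignmentHit]:
    """Local-alignment hits of one query against a subject set.

    ``query`` is a sequence string or an ``(id, sequence)`` pair; ``subjects``
    may be a prebuilt :class:`SubjectIndex` to amortize indexing across
    queries. Both strands are searched; hits above ``evalue_max`` are
    dropped (pass ``None`` to keep every positive-scoring alignment).
    """
    qid, qseq = query if isinstance(query, tuple) else ("query", query)
    if not qseq:
        raise ValueError("empty query sequence")
    index = subjects if isinstance(subjects, SubjectIndex) else SubjectIndex(subjects)
    return [
        AlignmentHit(
            query_id=qid,
            subject_id=h.subject_id,
            identity=h.identity,
            align_len=h.align_len,
            q_start=h.q_start,
            q_end=h.q_end,
            e_value=h.e_value,
            s_start=h.s_start,
            s_end=h.s_end,
            score=h.score,
        )
        for h in search(qseq, index, evalue_max)
    ]


def ani_score(hits: list[AlignmentHit], query_len: int) -> ANIResult:
    """Integrated ANI of one query from its hit list (empty list scores 0)."""
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    if not hits:
        return ANIResult(ani=0.0, mcov=0.0, n_hits=0)
    covered = np.zeros(query_len, dtype=bool)
    num = 0.0
    den = 0.0
    for h in hits:
        if h.q_start < 1 or h.q_end > query_len:
            raise ValueError(
                f"hit interval [{h.q_start},{h.q_end}] outside query of {query_len} bp"
            )
        num += h.identity * h.align_len
        den += h.align_len
        covered[h.q_start - 1 : h.q_end] = True
    mcov = float(covered.sum()) / query_len
    return ANIResult(ani=(num / den) * mcov, mcov=mcov, n_hits=len(hits))


def weighted_bin_ani(parts: list[tuple[float, int]]) -> float:
    """Length-weighted mean of per-contig ANIs."""
    if not parts:
        raise ValueError("weighted ANI of an empty bin is undefined")
    if any(l <= 0 for _, l in parts):
        raise ValueError("contig lengths must be positive")
    total = sum(l for _, l in parts)
    return sum(a * l for a, l in parts) / total


def ani_to_db(
    query_seqs: list[tuple[str, str]],
    db: list[tuple[str, str]] | SubjectIndex,
    evalue_max: float | None = DEFAULT_EVALUE,
) -> ANIResult:
    """Weighted ANI of a (possibly multi-contig) query set toward a database.

    Each query sequence is scored separately with the integrated ANI and the
    results combined length-weighted.
    """
    index = db if isinstance(db, SubjectIndex) else SubjectIndex(db)
    parts = []
    n_hits = 0
    cov_bp = 0
    total_bp = 0
    for qid, qseq in query_seqs:
        res = ani_score(find_hits((qid, qseq), index, evalue_max), len(qseq))
        parts.append((res.ani, len(qseq)))
        n_hits += res.n_hits
        cov_bp += int(round(res.mcov * len(qseq)))
        total_bp += len(qseq)
    return ANIResult(
        ani=weighted_bin_ani(parts),
        mcov=cov_bp / total_bp if total_bp else 0.0,
        n_hits=n_hits,
        per_contig=parts,
    )


def best_reference(
    bin_seqs: list[tuple[str, str]],
    refdb: list[tuple[str, str]],
    evalue_max: float | None = DEFAULT_EVALUE,
) -> list[tuple[str, float]]:
    """Rank references by their ANI toward the bin.

    Direction matters: each reference genome is the query and the bin's
    contigs form the database, so the reported ANI is "how much of this
    reference is recovered in the bin". Ties are broken by longer reference,
    then lexicographic id. Returns the full ranking.
    """
    if not refdb:
        raise ValueError("empty reference set")
    bin_index = SubjectIndex(bin_seqs)
    ranked = []
    for rid, rseq in refdb:
        res = ani_score(find_hits((rid, rseq), bin_index, evalue_max), len(rseq))
        ranked.append((rid, res.ani, len(rseq)))
    ranked.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [(rid, ani) for rid, ani, _ in ranked]


def is_phage(
    bin_seqs: list[tuple[str, str]],
    refdb: list[tuple[str, str]] | SubjectIndex,
    threshold: float = PHAGE_ANI_THRESHOLD,
) -> bool:
    """Phage / non-phage call: weighted bin ANI toward the reference set,
    inclusive at the threshold."""
    return ani_to_db(bin_seqs, refdb).ani >= threshold


def _fragments(seqs: list[tuple[str, str]], frag_len: int) -> list[tuple[str, str]]:
    frags = []
    for sid, seq in seqs:
        if len(seq) <= frag_len:
            frags.append((f"{sid}|0", seq))
            continue
        for i, start in enumerate(range(0, len(seq) - frag_len + 1, frag_len)):
            frags.append((f"{sid}|{i}", seq[start : start + frag_len]))
    return frags


def _best_frag_hits(
    frags_q: list[tuple[str, str]], frags_s: list[tuple[str, str]]
) -> dict[str, tuple[str, float]]:
    """Best subject fragment (by score) for each query fragment."""
    index = SubjectIndex(frags_s)
    best: dict[str, tuple[str, float]] = {}
    for fid, fseq in frags_q:
        hits = search(fseq, index, evalue_max=DEFAULT_EVALUE)
        if hits:
            best[fid] = (hits[0].subject_id, hits[0].identity)
    return best


def reciprocal_ani(
    seqs_a: list[tuple[str, str]],
    seqs_b: list[tuple[str, str]],
    frag_len: int = ORTHO_FRAG_LEN,
) -> float:
    """Orthologous-fragment reciprocal ANI between two sequence sets.

    Both sides are cut into ``frag_len`` fragments; fragment pairs that are
    each other's best hit are the orthologous pairs, and the returned value
    is the mean of both directions' identities over those pairs. Symmetric
    by construction; 0 when no reciprocal pair exists.
    """
    if not seqs_a or not seqs_b:
        raise ValueError("both sequence sets must be non-empty")
    fa = _fragments(seqs_a, frag_len)
    fb = _fragments(seqs_b, frag_len)
    # evaluate in a fixed orientation so value(a,b) == value(b,a) exactly
    swap = sorted(f[0] for f in fa) > sorted(f[0] for f in fb)
    if swap:
        fa, fb = fb, fa
    best_ab = _best_frag_hits(fa, fb)
    best_ba = _best_frag_hits(fb, fa)
    idents = []
    for qa, (sb, ident_ab) in best_ab.items():
        back = best_ba.get(sb)
        if back is not None and back[0] == qa:
            idents.append(0.5 * (ident_ab + back[1]))
    return float(np.mean(idents)) if idents else 0.0


def _kmer_set(seq_or_seqs, k: int) -> np.ndarray:
    if isinstance(seq_or_seqs, str):
        seqs = [seq_or_seqs]
    else:
        seqs = [s for _, s in seq_or_seqs]
    parts = [canonical_kmers(encode(s), k) for s in seqs if len(s) >= k]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def predict_host(
    bin_seqs: list[tuple[str, str]],
    host_db: list[tuple[str, str, str]],
    k: int = HOST_KMER,
    top: int = HOST_TOP_HITS,
    min_frac: float = 1e-3,
    _db_cache: dict | None = None,
) -> HostPrediction:
    """Predict the bacterial host of a bin by shared canonical k-mers.

    For every database phage the fraction of the bin's distinct canonical
    k-mers it shares is computed; phages are ranked and the host most
    represented among the ``top`` hits wins. The score is the mean shared
    fraction of the winning host's phages within those top hits; predictions
    with score <= 0.1 are unreliable.

    ``min_frac`` excludes chance matches from the vote: unrelated genomes of
    tens of kb collide on ~1e-4 of their 16-mers, while genuine homology
    retains (1-d)^16 of them — about 0.03 even at 20% divergence — so the
    default floor of 1e-3 sits between the two regimes.
    """
    if not host_db:
        raise ValueError("empty host database")
    bin_kmers = _kmer_set(bin_seqs, k)
    if len(bin_kmers) == 0:
        return HostPrediction(host=None, score=0.0, reliable=False)
    scored = []
    for pid, seq, host in host_db:
        if _db_cache is not None:
            db_kmers = _db_cache.get(pid)
            if db_kmers is None:
                db_kmers = _db_cache[pid] = _kmer_set(seq, k)
        else:
            db_kmers = _kmer_set(seq, k)
        shared = len(np.intersect1d(bin_kmers, db_kmers, assume_unique=True))
        scored.append((shared / len(bin_kmers), pid, host))
    scored.sort(key=lambda t: (-t[0], t[1]))
    # only phages sharing more than chance-level sequence can carry a vote
    top_hits = [t for t in scored[:top] if t[0] >= min_frac]
    if not top_hits:
        return HostPrediction(host=None, score=0.0, reliable=False)
    votes: dict[str, list[float]] = {}
    for frac, _, host in top_hits:
        votes.setdefault(host, []).append(frac)
    host, fracs = max(votes.items(), key=lambda kv: (len(kv[1]), sum(kv[1])))
    score = min(1.0, float(np.mean(fracs)))
    return HostPrediction(
        host=host,
        score=score,
        reliable=score > HOST_RELIABLE_SCORE,
        top_hits=[(pid, frac) for frac, pid, _ in top_hits],
    )


def read_tabular_hits(path, query_id: str | None = None) -> list[AlignmentHit]:
    """Ingest 12-column tabular hits (query, subject, %id, length, mismatches,
    gap opens, qstart, qend, sstart, send, evalue, bitscore)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"expected 12 tab-separated columns, got {len(f)}")
            if query_id is not None and f[0] != query_id:
                continue
            qs, qe = int(f[6]), int(f[7])
            hits.append(
                AlignmentHit(
                    query_id=f[0],
                    subject_id=f[1],
                    identity=float(f[2]),
                    align_len=int(f[3]),
                    q_start=min(qs, qe),
                    q_end=max(qs, qe),
                    e_value=float(f[10]),
                    s_start=int(f[8]),
                    s_end=int(f[9]),
                    score=float(f[11]),
                )
            )
    return hits


def write_tabular_hits(path, hits: list[AlignmentHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.identity:.3f}",
                        h.align_len,
                        "0",
                        "0",
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.e_value:.3g}",
                        f"{h.score:.1f}",
                    )
                )
                + "\n"
            )
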
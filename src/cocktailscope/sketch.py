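"""Bottom-s MinHash sketches of read sets and bootstrap composition distances.

A sample's reads are decomposed into canonical k-mers (k = 16), hashed with
a seeded 64-bit mixer, and reduced to the s (= 400) smallest hashes among
k-mers seen at least ``min_copies`` (= 2) times — the multiplicity floor
suppresses k-mers created by isolated sequencing errors. The Jaccard index
j of two sketches is estimated from the merged bottom-s of their union, and
converted to a global mutation distance via the Poisson model

    D = -(1/k) * ln(2j / (1 + j)),   D(j=1) = 0,  D(j=0) capped at 1.

Distance uncertainty comes from resampling read pairs with replacement
(default 100 replicates), rebuilding all sketches per replicate, and taking
the per-pair mean and standard error across replicate distance tables.

Hash values are implementation-specific (a splitmix64 finalizer, seeded);
distances are comparable only between sketches built with the same k, s and
hash seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from ._seq import encode, kmer_codes, revcomp_codes

DEFAULT_K = 16
DEFAULT_SKETCH_SIZE = 400
DEFAULT_MIN_COPIES = 2
DEFAULT_REPS = 100

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer (uint64 in, uint64 out)."""
    z = x + _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def hash_kmers(kmers: np.ndarray, hash_seed: int = 42) -> np.ndarray:
    """Seeded 64-bit hashes of integer k-mer codes."""
    x = kmers.astype(np.uint64) ^ _splitmix64(np.array([hash_seed], dtype=np.uint64))
    return _splitmix64(x)


@dataclass
class Sketch:
    k: int
    s: int
    min_copies: int
    hash_seed: int
    hashes: np.ndarray  # sorted ascending, <= s entries
    n_kmers: int = 0  # qualifying k-mer occurrences the sketch summarizes
    n_short_reads: int = 0  # reads shorter than k, skipped

    def compatible(self, other: "Sketch") -> bool:
        return (
            self.k == other.k and self.s == other.s and self.hash_seed == other.hash_seed
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "s": self.s,
                "min_copies": self.min_copies,
                "hash_seed": self.hash_seed,
                "hashes": [int(h) for h in self.hashes],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Sketch":
        d = json.loads(text)
        return cls(
            k=d["k"],
            s=d["s"],
            min_copies=d["min_copies"],
            hash_seed=d["hash_seed"],
            hashes=np.array(sorted(d["hashes"]), dtype=np.uint64),
        )


@dataclass
class DistanceEstimate:
    """Point distance plus bootstrap uncertainty.

    ``bootstrap_sd`` is the replicate standard deviation — the bootstrap
    estimate of the point estimator's sampling error, the scale on which
    the estimate should be compared with an external truth.
    ``bootstrap_se`` is ``sd / sqrt(reps)``, the Monte-Carlo error of the
    bootstrap mean — the much smaller ± figure conventionally printed next
    to the mean in distance tables.
    """

    d: float
    jaccard: float
    bootstrap_mean: float = float("nan")
    bootstrap_sd: float = float("nan")
    bootstrap_se: float = float("nan")
    reps: int = 0


def _read_kmer_hashes(
    seqs: list[str], k: int, hash_seed: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Canonical k-mer hashes of many reads, with the read index per k-mer."""
    n_short = sum(1 for s in seqs if len(s) < k)
    joined = "N".join(seqs)
    codes = encode(joined)
    kmers, valid = kmer_codes(codes, k)
    pos = np.flatnonzero(valid)
    kmers = kmers[pos]
    canon = np.minimum(kmers, revcomp_codes(kmers, k))
    hashes = hash_kmers(canon, hash_seed)
    # read index of each k-mer from its position in the joined string
    starts = np.cumsum([0] + [len(s) + 1 for s in seqs[:-1]]) if seqs else np.array([0])
    read_idx = np.searchsorted(starts, pos, side="right") - 1
    return hashes, read_idx.astype(np.int64), n_short


def make_sketch(
    reads,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    min_copies: int = DEFAULT_MIN_COPIES,
    hash_seed: int = 42,
) -> Sketch:
    """Bottom-s sketch of a read set (or any iterable of sequences).

    ``reads`` may be sequence strings or ``(id, seq, qual)`` records. Reads
    shorter than k are skipped and counted in ``n_short_reads``.
    """
    if k > 32:
        raise ValueError("k must be <= 32")
    seqs = [r if isinstance(r, str) else r[1] for r in reads]
    hashes, _, n_short = _read_kmer_hashes(seqs, k, hash_seed)
    if len(hashes) == 0:
        return Sketch(k, s, min_copies, hash_seed, np.empty(0, dtype=np.uint64),
                      n_short_reads=n_short)
    uniq, counts = np.unique(hashes, return_counts=True)
    qualifying = uniq[counts >= min_copies]
    bottom = qualifying[:s]  # uniq is sorted ascending already
    return Sketch(
        k, s, min_copies, hash_seed, bottom,
        n_kmers=int(counts[counts >= min_copies].sum()), n_short_reads=n_short,
    )


def jaccard(a: Sketch, b: Sketch) -> float:
    """Merged bottom-s Jaccard estimate between two sketches."""
    if not a.compatible(b):
        raise ValueError("sketches built with different k, s or hash seed")
    if len(a.hashes) == 0 or len(b.hashes) == 0:
        return 0.0
    union = np.union1d(a.hashes, b.hashes)
    merged = union[: min(a.s, len(union))]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = int(np.isin(merged, shared, assume_unique=False).sum())
    return n_shared / len(merged)


def mash_distance(j: float, k: int = DEFAULT_K) -> float:
    """Global mutation distance from a Jaccard index, capped to [0, 1]."""
    if not (0.0 <= j <= 1.0):
        raise ValueError("jaccard index must lie in [0, 1]")
    if j == 0.0:
        return 1.0
    d = -(1.0 / k) * math.log(2.0 * j / (1.0 + j))
    return min(1.0, max(0.0, d))


def sketch_distance(a: Sketch, b: Sketch) -> DistanceEstimate:
    j = jaccard(a, b)
    return DistanceEstimate(d=mash_distance(j, a.k), jaccard=j)


class _SampleKmers:
    """Per-sample canonical k-mers factorized once for fast resketching.

    Each bootstrap replicate then reduces to two bincounts (read draw
    counts, k-mer multiplicities) plus hashing the qualifying distinct
    k-mers.
    """

    def __init__(self, seqs: list[str], k: int):
        import hashlib

        self.n_reads = len(seqs)
        # content digest: samples with identical reads resample identically,
        # so D(x, x) is zero in every bootstrap replicate, not just on average
        self.content_key = int.from_bytes(
            hashlib.blake2b("\n".join(seqs).encode(), digest_size=8).digest(), "big"
        ) % (2**63)
        joined = "N".join(seqs)
        codes = encode(joined)
        kmers, valid = kmer_codes(codes, k)
        pos = np.flatnonzero(valid)
        kmers = kmers[pos]
        canon = np.minimum(kmers, revcomp_codes(kmers, k))
        starts = np.cumsum([0] + [len(t) + 1 for t in seqs[:-1]]) if seqs else np.array([0])
        read_idx = (np.searchsorted(starts, pos, side="right") - 1).astype(np.int32)
        self.uniq, inverse = np.unique(canon, return_inverse=True)
        self.inverse = inverse.astype(np.int32)
        self.read_idx = read_idx
        self.full_counts = np.bincount(self.inverse, minlength=len(self.uniq))

    def sketch_hashes(
        self, s: int, min_copies: int, hash_seed: int,
        read_counts: np.ndarray | None = None,
    ) -> np.ndarray:
        """Bottom-s hashes, optionally under a resampled read multiset."""
        if read_counts is None:
            counts = self.full_counts
        else:
            counts = np.bincount(
                self.inverse,
                weights=read_counts[self.read_idx].astype(float),
                minlength=len(self.uniq),
            )
        qualifying = self.uniq[counts >= min_copies]
        hh = hash_kmers(qualifying, hash_seed)
        if len(hh) <= s:
            return np.sort(hh)
        return np.sort(np.partition(hh, s)[:s])


def bootstrap_distances(
    samples: dict[str, list],
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    min_copies: int = DEFAULT_MIN_COPIES,
    hash_seed: int = 42,
    vary_hash: bool = False,
) -> tuple[dict[tuple[str, str], DistanceEstimate], list[np.ndarray]]:
    """Pairwise distance table with read-resampling bootstrap errors.

    ``samples`` maps sample id -> reads (strings or FASTQ records). Returns
    the per-pair estimates (point value from the full data; mean and
    standard error over ``reps`` resampled tables) and the list of replicate
    distance matrices in sample-id order.

    With ``vary_hash=False`` (the classic procedure) every replicate reuses
    the same hash function, so at high coverage — where resampling barely
    perturbs the k-mer set — the replicate spread reflects only read-
    sampling noise and understates the bottom-s sketch sampling error.
    ``vary_hash=True`` re-draws the hash seed per replicate (shared across
    samples within a replicate), making the replicate spread a variance-
    complete estimate of the estimator's sampling error; use it when
    comparing the distance against an external truth.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    names = list(samples)
    prepped = {
        name: _SampleKmers([r if isinstance(r, str) else r[1] for r in samples[name]], k)
        for name in names
    }
    rng = np.random.default_rng(seed)
    sample_rngs = {
        n: np.random.default_rng([seed, prepped[n].content_key]) for n in names
    }

    def table(sketches: dict[str, np.ndarray], hseed: int) -> np.ndarray:
        mat = np.zeros((len(names), len(names)))
        sk = {n: Sketch(k, s, min_copies, hseed, h) for n, h in sketches.items()}
        for i, a in enumerate(names):
            for jdx in range(i + 1, len(names)):
                b = names[jdx]
                d = mash_distance(jaccard(sk[a], sk[b]), k)
                mat[i, jdx] = mat[jdx, i] = d
        return mat

    point = table(
        {n: prepped[n].sketch_hashes(s, min_copies, hash_seed) for n in names}, hash_seed
    )
    tables = []
    for _ in range(reps):
        hseed = int(rng.integers(0, 2**31)) if vary_hash else hash_seed
        sketches = {}
        for n in names:
            sample = prepped[n]
            draw = sample_rngs[n].integers(0, sample.n_reads, sample.n_reads)
            read_counts = np.bincount(draw, minlength=sample.n_reads)
            sketches[n] = sample.sketch_hashes(s, min_copies, hseed, read_counts)
        tables.append(table(sketches, hseed))
    stack = np.stack(tables)
    means = stack.mean(axis=0)
    sds = stack.std(axis=0, ddof=1)
    out = {}
    for i, a in enumerate(names):
        for jdx in range(i + 1, len(names)):
            b = names[jdx]
            out[(a, b)] = DistanceEstimate(
                d=float(point[i, jdx]),
                jaccard=float("nan"),
                bootstrap_mean=float(means[i, jdx]),
                bootstrap_sd=float(sds[i, jdx]),
                bootstrap_se=float(sds[i, jdx]) / math.sqrt(reps),
                reps=reps,
            )
    return out, tables
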
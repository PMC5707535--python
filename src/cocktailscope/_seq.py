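"""Low-level DNA sequence helpers shared across modules.

Sequences cross module boundaries as plain Python strings over {A,C,G,T,N};
internally most numerics run on numpy uint8 code arrays (A=0, C=1, G=2, T=3,
anything else = 4).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.empty(len(codes), dtype=np.uint8)
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    np.copyto(out, lut[codes])
    return out.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes (base-4) and a validity mask.

    Returns (kmers, valid) of length len(codes)-k+1; windows containing a
    non-ACGT base are marked invalid (their code is meaningless).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    safe = np.where(codes >= 4, 0, codes).astype(np.int64)
    kmers = np.zeros(n, dtype=np.int64)
    for j in range(k):
        kmers = kmers * 4 + safe[j : j + n]
    return kmers, valid


def revcomp_codes(kmers: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of base-4 k-mer integer codes, vectorized."""
    rc = np.zeros_like(kmers)
    tmp = kmers.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp & 3))
        tmp >>= 2
    return rc


def canonical_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Distinct-position canonical (min of strand pair) k-mers, invalid dropped."""
    kmers, valid = kmer_codes(codes, k)
    kmers = kmers[valid]
    return np.minimum(kmers, revcomp_codes(kmers, k))


def write_fasta(path, records) -> None:
    """Write (id, seq) pairs as FASTA, 80-column wrapped."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
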
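"""Quality trimming, control spike-in removal, and mate re-synchronization.

Trimming follows the classic short-read recipe for 250-bp paired-end data:
fixed trims first (20 bp from the 5' end, 10 bp from the 3' end — adapter
and chemistry artifacts), then per-base 3' quality trimming at Phred 20,
then filters on mean quality (>= 20) and length (>= 35), then dereplication
of exact and exact reverse-complement duplicates per mate file. Pairs whose
mates survive unevenly are re-synchronized by read identifier, with
unmatched survivors routed to an orphan pool.

Spike-in (sequencing-control) reads are detected by a word-seeded match to
the control genome: any read with a >= 50 bp stretch at >= 90% identity to
the control, on either strand, is treated as control contamination and the
whole pair removed. This is robust to ~1% sequencing error without pulling
in a full aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, kmer_codes, revcomp
from .seq_synth import FastqRead


class FormatError(ValueError):
    """Malformed or inconsistent read input."""


@dataclass
class TrimConfig:
    trim_left: int = 20
    trim_right: int = 10
    trim_qual_right: int = 20
    min_qual_mean: int = 20
    min_len: int = 35
    derep_exact: bool = True
    derep_revcomp: bool = True

    def __post_init__(self) -> None:
        if min(self.trim_left, self.trim_right, self.trim_qual_right, self.min_qual_mean) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class QCStats:
    reads_in: int = 0
    reads_after_trim: int = 0
    reads_after_spike_removal: int = 0
    orphans: int = 0
    discarded: int = 0
    duplicates: int = 0
    bp_in: int = 0
    bp_out: int = 0


def _trim_one(read: FastqRead, cfg: TrimConfig) -> FastqRead | None:
    rid, seq, qual = read
    seq = seq[cfg.trim_left :]
    qual = qual[cfg.trim_left :]
    if cfg.trim_right:
        seq = seq[: -cfg.trim_right] or ""
        qual = qual[: -cfg.trim_right] or ""
    end = len(qual)
    while end > 0 and ord(qual[end - 1]) - 33 < cfg.trim_qual_right:
        end -= 1
    seq, qual = seq[:end], qual[:end]
    if len(seq) < cfg.min_len:
        return None
    q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
    if q.mean() < cfg.min_qual_mean:
        return None
    return (rid, seq, qual)


def trim_reads(
    fwd: list[FastqRead], rev: list[FastqRead], cfg: TrimConfig | None = None
) -> tuple[list[FastqRead], list[FastqRead], list[FastqRead], QCStats]:
    """Trim both mate files and re-pair the survivors.

    Returns ``(fwd_out, rev_out, orphans, stats)``. Surviving reads whose
    mate was discarded (or dereplicated) go to ``orphans``; output pairs
    keep the input order. Duplicate removal keeps the first occurrence.
    """
    cfg = cfg or TrimConfig()
    if len(fwd) != len(rev):
        raise FormatError(f"mate files differ in read count: {len(fwd)} vs {len(rev)}")
    stats = QCStats(reads_in=2 * len(fwd), bp_in=sum(len(s) for _, s, _ in fwd + rev))
    survivors: list[list[FastqRead | None]] = [[], []]
    for mate_idx, reads in enumerate((fwd, rev)):
        seen: set[str] = set()
        for read in reads:
            out = _trim_one(read, cfg)
            if out is None:
                stats.discarded += 1
                survivors[mate_idx].append(None)
                continue
            if cfg.derep_exact or cfg.derep_revcomp:
                key = out[1]
                rc = revcomp(key)
                dup = (cfg.derep_exact and key in seen) or (
                    cfg.derep_revcomp and rc in seen
                )
                if dup:
                    stats.duplicates += 1
                    survivors[mate_idx].append(None)
                    continue
                seen.add(key)
            survivors[mate_idx].append(out)
    fwd_out, rev_out, orphans = [], [], []
    for f, r in zip(*survivors):
        if f is not None and r is not None:
            fwd_out.append(f)
            rev_out.append(r)
        elif f is not None:
            orphans.append(f)
        elif r is not None:
            orphans.append(r)
    stats.orphans = len(orphans)
    stats.reads_after_trim = 2 * len(fwd_out)
    stats.bp_out = sum(len(s) for _, s, _ in fwd_out + rev_out)
    return fwd_out, rev_out, orphans, stats


class SpikeDetector:
    """Word-seeded matcher against a control genome (both strands)."""

    def __init__(self, control_genome: str, word: int = 21, min_span: int = 50,
                 min_identity: float = 0.9):
        if not control_genome:
            raise ValueError("control genome must be non-empty")
        self.word = word
        self.min_span = min_span
        self.min_identity = min_identity
        self._strands = [encode(control_genome), encode(revcomp(control_genome))]
        self._index: dict[int, list[tuple[int, int]]] = {}
        for strand, codes in enumerate(self._strands):
            km, valid = kmer_codes(codes, word)
            for pos in np.flatnonzero(valid):
                self._index.setdefault(int(km[pos]), []).append((strand, int(pos)))

    def matches(self, seq: str) -> bool:
        if len(seq) < self.min_span:
            return False
        codes = encode(seq)
        km, valid = kmer_codes(codes, self.word)
        checked: set[tuple[int, int]] = set()
        for qpos in range(0, len(km), 7):  # seeds every 7 bp: an error-free
            # word survives any <=3 errors per 42 bp window
            if not valid[qpos]:
                continue
            for strand, spos in self._index.get(int(km[qpos]), ()):  # noqa: B905
                diag = qpos - spos
                if (strand, diag) in checked:
                    continue
                checked.add((strand, diag))
                ctrl = self._strands[strand]
                lo = max(0, diag)
                hi = min(len(codes), len(ctrl) + diag)
                if hi - lo < self.min_span:
                    continue
                m = codes[lo:hi] == ctrl[lo - diag : hi - diag]
                span = hi - lo
                if span >= self.min_span and m.sum() / span >= self.min_identity:
                    return True
                # best window of exactly min_span within the diagonal
                if span > self.min_span:
                    cs = np.concatenate([[0], np.cumsum(m)])
                    wins = cs[self.min_span :] - cs[: -self.min_span]
                    if wins.max() / self.min_span >= self.min_identity:
                        return True
        return False


def remove_spike(
    fwd: list[FastqRead],
    rev: list[FastqRead],
    control_genome: str,
) -> tuple[list[FastqRead], list[FastqRead], int]:
    """Drop pairs where either mate matches the control genome.

    Returns ``(fwd_out, rev_out, removed_pair_count)``; input order is
    preserved.
    """
    det = SpikeDetector(control_genome)
    fwd_out, rev_out, removed = [], [], 0
    for f, r in zip(fwd, rev):
        if det.matches(f[1]) or det.matches(r[1]):
            removed += 1
        else:
            fwd_out.append(f)
            rev_out.append(r)
    return fwd_out, rev_out, removed


def _pair_key(rid: str) -> str:
    for suffix in ("/1", "/2"):
        if rid.endswith(suffix):
            return rid[:-2]
    return rid.split()[0]


def repair_pairs(
    fwd: list[FastqRead], rev: list[FastqRead]
) -> tuple[list[FastqRead], list[FastqRead], list[FastqRead]]:
    """Re-synchronize two mate files by read identifier.

    Output follows the forward-file order; reads without a mate are returned
    as orphans. Duplicate identifiers within one file are a format error.
    """
    rev_by_id: dict[str, FastqRead] = {}
    for read in rev:
        key = _pair_key(read[0])
        if key in rev_by_id:
            raise FormatError(f"duplicate read id in reverse file: {key}")
        rev_by_id[key] = read
    fwd_keys = set()
    fwd_out, rev_out, orphans = [], [], []
    for read in fwd:
        key = _pair_key(read[0])
        if key in fwd_keys:
            raise FormatError(f"duplicate read id in forward file: {key}")
        fwd_keys.add(key)
        mate = rev_by_id.pop(key, None)
        if mate is None:
            orphans.append(read)
        else:
            fwd_out.append(read)
            rev_out.append(mate)
    orphans.extend(rev_by_id.values())
    return fwd_out, rev_out, orphans
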
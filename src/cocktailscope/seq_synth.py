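"""Synthetic phage cocktails with full ground truth.

Every downstream stage of the pipeline (trimming, binning, ANI annotation,
classification, abundance and sketch distances) is exercised on synthetic
cocktails built here, so recovery against a known truth is testable without
any external downloads.

Genomes are emitted from independent order-3 Markov models (per-genome
transition rows drawn from a uniform Dirichlet), which gives each genome a
distinct low-order compositional signature — the property tetranucleotide-
frequency binning relies on. Relatives are derived by point substitution at
a controlled rate; cocktail abundances are drawn log-uniformly over a
configurable span (default up to 1000-fold, the order of magnitude seen
between the most and least abundant members of real therapeutic cocktails).
Reads are 250 bp paired-end with uniform substitution errors and a quality
profile whose 3' tail degrades predictably so the trimmer has work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, revcomp

# FASTQ read record: (id, sequence, quality string, Phred+33)
FastqRead = tuple[str, str, str]


class ParameterError(ValueError):
    """Raised when a generator is called with out-of-range parameters."""


@dataclass
class SyntheticPhage:
    """A synthetic phage genome with known provenance."""

    id: str
    sequence: str
    host_label: str
    parent_id: str | None = None
    divergence: float = 0.0
    markov_model: np.ndarray | None = None  # shape (64, 4) transition rows

    def __post_init__(self) -> None:
        if set(self.sequence) - set(BASES):
            raise ParameterError(f"{self.id}: sequence has non-ACGT characters")
        if (self.parent_id is None) != (self.divergence == 0.0):
            raise ParameterError(f"{self.id}: divergence=0 iff no parent")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CocktailSample:
    """A mixture of phages with positive, normalized abundance weights."""

    id: str
    members: list[tuple[str, float]]
    abundance_cap: float = 1000.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ParameterError("cocktail must have at least one member")
        w = np.array([wt for _, wt in self.members], dtype=float)
        if np.any(w <= 0):
            raise ParameterError("abundance weights must be positive")
        span = w.max() / w.min()
        if span > self.abundance_cap * (1 + 1e-9):
            raise ParameterError(
                f"abundance span {span:.1f} exceeds cap {self.abundance_cap}"
            )
        w = w / w.sum()
        self.members = [(pid, float(wi)) for (pid, _), wi in zip(self.members, w)]

    @property
    def abundance_span(self) -> float:
        w = [wt for _, wt in self.members]
        return max(w) / min(w)

    def weights(self) -> dict[str, float]:
        return dict(self.members)


@dataclass
class GroundTruth:
    """Provenance tables for synthetic reads, contigs and mixtures."""

    read_origin: dict[str, str] = field(default_factory=dict)
    contig_origin: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    true_abundance: dict[str, dict[str, float]] = field(default_factory=dict)
    true_divergence: dict[tuple[str, str], float] = field(default_factory=dict)
    shared_members: set[str] = field(default_factory=set)
    below_min_contigs: set[str] = field(default_factory=set)


def _emit_markov(model: np.ndarray, length: int, rng: np.random.Generator) -> str:
    """Emit a sequence of `length` bases from an order-3 model."""
    cumrows = np.cumsum(model, axis=1)
    cumrows[:, -1] = 1.0
    out = np.empty(length, dtype=np.uint8)
    out[:3] = rng.integers(0, 4, size=3)
    ctx = int(out[0]) * 16 + int(out[1]) * 4 + int(out[2])
    u = rng.random(length)
    cr = cumrows  # local alias for the hot loop
    for i in range(3, length):
        row = cr[ctx]
        ui = u[i]
        b = 0
        while row[b] < ui:
            b += 1
        out[i] = b
        ctx = ((ctx * 4) & 63) + b
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[out].tobytes().decode("ascii")


def generate_phage_db(
    n_genomes: int,
    length_range: tuple[int, int] = (20_000, 60_000),
    n_hosts: int = 4,
    seed: int = 0,
) -> tuple[list[SyntheticPhage], GroundTruth]:
    """Generate `n_genomes` phage genomes, each from its own order-3 model.

    Host labels are assigned round-robin over ``n_hosts`` synthetic species
    names. Deterministic given ``seed``.
    """
    lo, hi = length_range
    if n_genomes < 1:
        raise ParameterError("n_genomes must be >= 1")
    if not (4 <= lo <= hi):
        raise ParameterError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    phages = []
    for g in range(n_genomes):
        model = rng.dirichlet(np.ones(4), size=64)
        length = int(rng.integers(lo, hi + 1))
        seq = _emit_markov(model, length, rng)
        phages.append(
            SyntheticPhage(
                id=f"phage{g:02d}",
                sequence=seq,
                host_label=f"Host_sp{g % n_hosts}",
                markov_model=model,
            )
        )
    return phages, GroundTruth()


def derive_relative(
    parent: SyntheticPhage,
    sub_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    child_id: str | None = None,
) -> SyntheticPhage:
    """Derive a relative of ``parent`` by per-site substitution (and optional
    single-base indels) at the given rates."""
    if not (0 <= sub_rate < 0.5) or not (0 <= indel_rate < 0.5):
        raise ParameterError("rates must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    seq = list(parent.sequence)
    n = len(seq)
    sub_mask = rng.random(n) < sub_rate
    for i in np.flatnonzero(sub_mask):
        alts = [b for b in BASES if b != seq[i]]
        seq[i] = alts[rng.integers(0, 3)]
    if indel_rate > 0:
        out = []
        ins_or_del = rng.random(n) < indel_rate
        kind = rng.random(n) < 0.5
        for i, b in enumerate(seq):
            if ins_or_del[i]:
                if kind[i]:  # insertion before this base
                    out.append(BASES[rng.integers(0, 4)])
                    out.append(b)
                # else deletion: skip base
            else:
                out.append(b)
        seq = out
    cid = child_id or f"{parent.id}.rel"
    if sub_rate == 0 and indel_rate == 0:
        return SyntheticPhage(cid, parent.sequence, parent.host_label)
    return SyntheticPhage(
        cid, "".join(seq), parent.host_label, parent_id=parent.id, divergence=sub_rate
    )


def make_cocktail(
    sample_id: str,
    phage_ids: list[str],
    abundance_span: float = 1000.0,
    seed: int = 0,
) -> CocktailSample:
    """Draw log-uniform abundance weights over at most ``abundance_span``."""
    if not phage_ids:
        raise ParameterError("empty member list")
    rng = np.random.default_rng(seed)
    n = len(phage_ids)
    logw = rng.uniform(0.0, math.log10(abundance_span), size=n)
    logw -= logw.min()  # pin the span so min weight is exactly 1 pre-normalization
    w = 10.0**logw
    return CocktailSample(sample_id, list(zip(phage_ids, w)), abundance_cap=abundance_span)


def _quality_profile(read_len: int, tail: int = 25, q_hi: int = 37, q_lo: int = 5) -> str:
    """Phred+33 quality string: flat high-quality core, linear 3' decay.

    The decay is deterministic so the number of bases below any trimming
    threshold is a fixed function of read length.
    """
    q = np.full(read_len, q_hi, dtype=int)
    t = min(tail, read_len)
    q[read_len - t :] = np.linspace(q_hi, q_lo, t).round().astype(int)
    return "".join(chr(33 + int(x)) for x in q)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    for i in np.flatnonzero(rng.random(len(arr)) < error_rate):
        alts = [b for b in BASES if b != arr[i]]
        arr[i] = alts[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(
    sample: CocktailSample,
    db: list[SyntheticPhage],
    n_pairs: int,
    read_len: int = 250,
    error_rate: float = 0.01,
    spike_fraction: float = 0.0,
    spike_genome: str | None = None,
    seed: int = 0,
) -> tuple[list[FastqRead], list[FastqRead], GroundTruth]:
    """Simulate paired-end reads from a cocktail mixture.

    Per-genome pair counts are multinomial with probability proportional to
    abundance weight times genome length (longer genomes shed more fragments
    at equal molarity of genome copies... here weight is interpreted as the
    relative mass fraction times copy number; the product rule keeps abundance
    recovery linear). A ``spike_fraction`` of pairs is drawn from
    ``spike_genome`` when given, emulating a sequencing control.
    """
    if n_pairs < 0:
        raise ParameterError("n_pairs must be >= 0")
    by_id = {p.id: p for p in db}
    genomes = []
    probs = []
    for pid, wt in sample.members:
        if pid not in by_id:
            raise ParameterError(f"cocktail member {pid} not in database")
        genomes.append(by_id[pid])
        probs.append(wt * len(by_id[pid]))
    if spike_fraction > 0 and not spike_genome:
        raise ParameterError("spike_fraction > 0 requires a spike genome")
    shortest = min(len(g) for g in genomes)
    if read_len > shortest:
        raise ParameterError("read_len exceeds the shortest member genome")
    probs = np.array(probs) / np.sum(probs)
    rng = np.random.default_rng(seed)
    qual = _quality_profile(read_len)
    r1: list[FastqRead] = []
    r2: list[FastqRead] = []
    truth = GroundTruth(true_abundance={sample.id: sample.weights()})
    for i in range(n_pairs):
        rid = f"{sample.id}:{i:07d}"
        if spike_fraction > 0 and rng.random() < spike_fraction:
            src_seq, origin = spike_genome, "spike"
        else:
            g = genomes[rng.choice(len(genomes), p=probs)]
            src_seq, origin = g.sequence, g.id
        frag_len = int(rng.integers(read_len, min(len(src_seq), 2 * read_len) + 1))
        start = int(rng.integers(0, len(src_seq) - frag_len + 1))
        frag = src_seq[start : start + frag_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        fwd = _mutate(frag[:read_len], error_rate, rng)
        rev = _mutate(revcomp(frag)[:read_len], error_rate, rng)
        r1.append((rid + "/1", fwd, qual))
        r2.append((rid + "/2", rev, qual))
        truth.read_origin[rid] = origin
    return r1, r2, truth


def fragment_to_contigs(
    sample: CocktailSample,
    db: list[SyntheticPhage],
    frag_len_range: tuple[int, int] = (2_000, 10_000),
    dropout: float = 0.1,
    seed: int = 0,
    min_contig_flag: int = 2_000,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Fragment member genomes into contig-like substrings.

    Walks each genome alternating emitted fragments (uniform length in
    ``frag_len_range``) and uncovered gaps whose mean is set so the expected
    uncovered fraction equals ``dropout``. Truncated terminal fragments may
    fall below ``min_contig_flag`` and are flagged in the truth table, which
    lets tests exercise the binning length filter.
    """
    lo, hi = frag_len_range
    if lo < 1 or hi < lo:
        raise ParameterError(f"invalid fragment length range {frag_len_range}")
    if not (0 <= dropout < 1):
        raise ParameterError("dropout must lie in [0, 1)")
    by_id = {p.id: p for p in db}
    rng = np.random.default_rng(seed)
    contigs: list[tuple[str, str]] = []
    truth = GroundTruth(true_abundance={sample.id: sample.weights()})
    mean_frag = (lo + hi) / 2
    mean_gap = dropout / (1 - dropout) * mean_frag if dropout > 0 else 0.0
    for pid, _ in sample.members:
        genome = by_id[pid].sequence
        pos = 0
        idx = 0
        # lead-in gap so the first fragment does not always anchor at 0
        if dropout > 0:
            pos = int(rng.exponential(mean_gap / 2))
        while pos < len(genome):
            frag_len = int(rng.integers(lo, hi + 1))
            end = min(pos + frag_len, len(genome))
            if end - pos >= max(1, lo // 4):  # skip tiny terminal slivers
                cid = f"{pid}_c{idx}"
                contigs.append((cid, genome[pos:end]))
                truth.contig_origin[cid] = (pid, pos, end)
                if end - pos < min_contig_flag:
                    truth.below_min_contigs.add(cid)
                idx += 1
            pos = end
            if dropout > 0:
                pos += 1 + int(rng.exponential(mean_gap))
    return contigs, truth


def write_fastq(path, reads: list[FastqRead]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[FastqRead]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [(rid, seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]
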
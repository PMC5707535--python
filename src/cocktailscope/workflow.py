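"""End-to-end orchestration: characterize each cocktail sample, compare
samples, and emit report tables.

Stage order within a sample is fixed: trim -> spike removal -> bin ->
depth -> split -> annotate -> merge -> re-annotate -> phage/fragmented
flags -> host prediction. Annotation runs both before merging (merging
needs best references) and after (final ANIs belong to the merged bins).
Fragmented and non-phage bins are excluded from cross-sample pairing and
host prediction but retained in every report table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._align import SubjectIndex
from .ani import HostPrediction, ani_to_db, best_reference, predict_host
from .binning import Bin, Contig, bin_contigs
from .curation import (
    CATEGORY_LABELS,
    BinMatch,
    CoverageProfile,
    abundance_table,
    classify,
    depth_profile,
    internal_overlap,
    merge_bins,
    pair_bins,
    split_bin,
)
from .preprocess import TrimConfig, QCStats, remove_spike, trim_reads
from .sketch import DEFAULT_K, DEFAULT_MIN_COPIES, DEFAULT_SKETCH_SIZE, bootstrap_distances

logger = logging.getLogger("cocktailscope")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    min_contig: int = 2_000
    min_bin: int = 10_000
    link_threshold: float = 0.045
    cv_threshold: float = 0.1
    cov_tolerance: float = 0.25
    phage_ani_threshold: float = 10.0
    pair_ani_threshold: float = 70.0
    completeness_min: float = 0.9
    sketch_k: int = DEFAULT_K
    sketch_s: int = DEFAULT_SKETCH_SIZE
    sketch_min_copies: int = DEFAULT_MIN_COPIES
    bootstrap_reps: int = 100
    seed: int = 0
    trim: TrimConfig = field(default_factory=TrimConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        trim = TrimConfig(**raw.pop("trim", {}))
        return cls(trim=trim, **raw)


@dataclass
class CharacterizedSample:
    id: str
    contig_seqs: dict[str, str]
    bins: list[Bin]
    unbinned: list[str]
    profile: CoverageProfile
    annotations: dict[str, tuple[str, float, int]]  # bin -> (ref, ANI, ref_len)
    bin_db_ani: dict[str, float]  # bin (as query) toward the reference db
    is_phage_bin: dict[str, bool]
    fragmented: dict[str, bool]
    collapsed: dict[str, bool]
    hosts: dict[str, HostPrediction]
    reads: tuple[list, list]
    n_read_pairs: int
    qc: QCStats

    def bin_seqs(self, bin_id: str) -> list[tuple[str, str]]:
        b = next(x for x in self.bins if x.id == bin_id)
        return [(c, self.contig_seqs[c]) for c in b.contig_ids]

    def draft_genome_ids(self) -> list[str]:
        """Bins that are phage and not hopelessly fragmented."""
        return [
            b.id
            for b in self.bins
            if self.is_phage_bin[b.id] and not self.fragmented[b.id]
        ]


@dataclass
class Report:
    sample_ids: list[str]
    host_counts: pd.DataFrame
    matches: pd.DataFrame
    category_counts: pd.DataFrame
    annotations: dict[str, pd.DataFrame]
    abundance: pd.DataFrame
    distances: pd.DataFrame
    log: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "sample_ids": self.sample_ids,
            "host_counts": self.host_counts.to_dict(orient="records"),
            "matches": self.matches.to_dict(orient="records"),
            "category_counts": self.category_counts.to_dict(orient="records"),
            "annotations": {
                k: v.to_dict(orient="records") for k, v in self.annotations.items()
            },
            "abundance": self.abundance.to_dict(orient="records"),
            "distances": self.distances.to_dict(orient="records"),
            "log": self.log,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        d = json.loads(text)
        return cls(
            sample_ids=d["sample_ids"],
            host_counts=pd.DataFrame(d["host_counts"]),
            matches=pd.DataFrame(d["matches"]),
            category_counts=pd.DataFrame(d["category_counts"]),
            annotations={k: pd.DataFrame(v) for k, v in d["annotations"].items()},
            abundance=pd.DataFrame(d["abundance"]),
            distances=pd.DataFrame(d["distances"]),
            log=d.get("log", {}),
        )


def characterize_sample(
    sample_id: str,
    fwd_reads: list,
    rev_reads: list,
    contigs: list[tuple[str, str]],
    refdb: list[tuple[str, str]],
    host_db: list[tuple[str, str, str]] | None = None,
    spike_genome: str | None = None,
    config: PipelineConfig | None = None,
) -> CharacterizedSample:
    """Run the per-sample pipeline; deterministic given ``config.seed``."""
    cfg = config or PipelineConfig()
    logger.info("characterize %s: %d read pairs, %d contigs", sample_id,
                len(fwd_reads), len(contigs))
    fwd, rev, _orphans, qc = trim_reads(fwd_reads, rev_reads, cfg.trim)
    if spike_genome:
        fwd, rev, removed = remove_spike(fwd, rev, spike_genome)
        qc.reads_after_spike_removal = 2 * len(fwd)
        logger.info("%s: removed %d spike pairs", sample_id, removed)
    else:
        qc.reads_after_spike_removal = qc.reads_after_trim

    if not contigs:
        raise PipelineError("bin", f"{sample_id}: empty contig set")
    contig_seqs = dict(contigs)
    contig_objs = [Contig(cid, seq) for cid, seq in contigs]
    bins, unbinned = bin_contigs(
        contig_objs, cfg.min_contig, cfg.min_bin, cfg.link_threshold
    )
    if not bins:
        raise PipelineError("bin", f"{sample_id}: no bin reached {cfg.min_bin} bp")

    if not fwd:
        raise PipelineError("depth", f"{sample_id}: no reads survived preprocessing")
    profile = depth_profile(contigs, reads=(fwd, rev), seed=cfg.seed)

    bins = [sb for b in bins for sb in split_bin(b, profile, cfg.cv_threshold, cfg.min_bin)]

    def annotate(bs: list[Bin]) -> dict[str, tuple[str, float, int]]:
        ref_len = {rid: len(seq) for rid, seq in refdb}
        out = {}
        for b in bs:
            seqs = [(c, contig_seqs[c]) for c in b.contig_ids]
            ranked = best_reference(seqs, refdb)
            rid, ani = ranked[0]
            out[b.id] = (rid, ani, ref_len[rid])
        return out

    annotations = annotate(bins)
    bins = merge_bins(
        bins,
        {bid: ref for bid, (ref, _, _) in annotations.items()},
        profile,
        contig_seqs,
        cfg.cov_tolerance,
    )
    annotations = annotate(bins)

    ref_index = SubjectIndex(refdb)
    bin_db_ani = {}
    is_phage_bin = {}
    fragmented = {}
    collapsed = {}
    hosts: dict[str, HostPrediction] = {}
    kmer_cache: dict = {}
    for b in bins:
        seqs = [(c, contig_seqs[c]) for c in b.contig_ids]
        bin_db_ani[b.id] = ani_to_db(seqs, ref_index).ani
        is_phage_bin[b.id] = bin_db_ani[b.id] >= cfg.phage_ani_threshold
        lengths = [len(contig_seqs[c]) for c in b.contig_ids]
        fragmented[b.id] = len(lengths) > 20 and all(l < 7000 for l in lengths)
        _, ref_ani, ref_len = annotations[b.id]
        collapsed[b.id] = b.total_bp > 1.1 * ref_len and internal_overlap(seqs)
        if host_db and is_phage_bin[b.id] and not fragmented[b.id]:
            hosts[b.id] = predict_host(seqs, host_db, _db_cache=kmer_cache)
    return CharacterizedSample(
        id=sample_id,
        contig_seqs=contig_seqs,
        bins=bins,
        unbinned=unbinned,
        profile=profile,
        annotations=annotations,
        bin_db_ani=bin_db_ani,
        is_phage_bin=is_phage_bin,
        fragmented=fragmented,
        collapsed=collapsed,
        hosts=hosts,
        reads=(fwd, rev),
        n_read_pairs=len(fwd),
        qc=qc,
    )


def _annotation_frame(
    sample: CharacterizedSample, categories: dict[str, int]
) -> pd.DataFrame:
    rows = []
    for b in sample.bins:
        ref, ani, ref_len = sample.annotations[b.id]
        rows.append(
            {
                "bin": b.id,
                "n_contigs": len(b.contig_ids),
                "size_bp": b.total_bp,
                "closest_reference": ref,
                "reference_ani": round(ani, 3),
                "bin_to_db_ani": round(sample.bin_db_ani[b.id], 3),
                "is_phage": sample.is_phage_bin[b.id],
                "category": categories[b.id],
                "host": sample.hosts[b.id].host
                if b.id in sample.hosts and sample.hosts[b.id].reliable
                else "",
                "provenance": b.provenance,
            }
        )
    return pd.DataFrame(rows)


def compare_samples(
    a: CharacterizedSample,
    b: CharacterizedSample,
    extra_read_sets: dict[str, list] | None = None,
    config: PipelineConfig | None = None,
) -> Report:
    """Pair bins across two characterized samples and build the full report."""
    cfg = config or PipelineConfig()
    bins_a = {bid: a.bin_seqs(bid) for bid in a.draft_genome_ids()}
    bins_b = {bid: b.bin_seqs(bid) for bid in b.draft_genome_ids()}
    matches: list[BinMatch] = (
        pair_bins(bins_a, bins_b, cfg.pair_ani_threshold) if bins_a and bins_b else []
    )
    matched_a = {m.bin_a for m in matches}
    matched_b = {m.bin_b for m in matches}

    def categorize(sample: CharacterizedSample, matched: set[str]) -> dict[str, int]:
        cats = {}
        for bn in sample.bins:
            ref, ref_ani, ref_len = sample.annotations[bn.id]
            # the special-case ANI rule uses the bin-toward-database direction
            effective_ani = ref_ani if sample.is_phage_bin[bn.id] else 0.0
            cats[bn.id] = classify(
                bin_length=bn.total_bp,
                contig_lengths=[len(sample.contig_seqs[c]) for c in bn.contig_ids],
                ref_ani=effective_ani,
                ref_len=ref_len,
                has_counterpart=bn.id in matched,
                has_internal_overlap=sample.collapsed[bn.id],
                completeness_min=cfg.completeness_min,
                phage_ani_min=cfg.phage_ani_threshold,
                high_ani=cfg.pair_ani_threshold,
            )
        return cats

    cats_a = categorize(a, matched_a)
    cats_b = categorize(b, matched_b)

    match_rows = [
        {
            "bin_a": m.bin_a,
            "bin_b": m.bin_b,
            "ani_a_to_b": round(m.ani_a_to_b, 3),
            "ani_b_to_a": round(m.ani_b_to_a, 3),
            "reciprocal_ani": round(m.reciprocal_ani, 3),
            "host": a.hosts[m.bin_a].host
            if m.bin_a in a.hosts and a.hosts[m.bin_a].reliable
            else "",
        }
        for m in matches
    ]
    matches_df = pd.DataFrame(
        match_rows,
        columns=["bin_a", "bin_b", "ani_a_to_b", "ani_b_to_a", "reciprocal_ani", "host"],
    )

    cat_rows = [
        {
            "category": c,
            "label": CATEGORY_LABELS[c],
            a.id: sum(1 for v in cats_a.values() if v == c),
            b.id: sum(1 for v in cats_b.values() if v == c),
        }
        for c in range(1, 7)
    ]
    category_counts = pd.DataFrame(cat_rows)

    host_rows: dict[str, dict[str, int]] = {}
    for sample in (a, b):
        for bid, pred in sample.hosts.items():
            if pred.reliable and pred.host:
                host_rows.setdefault(pred.host, {a.id: 0, b.id: 0})[sample.id] += 1
    host_counts = pd.DataFrame(
        [{"host": h, **counts} for h, counts in sorted(host_rows.items())],
        columns=["host", a.id, b.id],
    )

    # cross-mapped abundances: each sample's bins covered by both read sets
    bin_depths: dict[str, dict[str, float]] = {}
    total_reads = {a.id: 2 * a.n_read_pairs, b.id: 2 * b.n_read_pairs}
    for own, other in ((a, b), (b, a)):
        contigs = list(own.contig_seqs.items())
        cross = depth_profile(contigs, reads=other.reads, seed=cfg.seed, keep_arrays=False)
        for bn in own.bins:
            bin_depths[f"{own.id}:{bn.id}"] = {
                own.id: own.profile.bin_mean(bn.contig_ids),
                other.id: cross.bin_mean(bn.contig_ids),
            }
    abundance = abundance_table(bin_depths, total_reads)

    read_sets = {a.id: a.reads[0] + a.reads[1], b.id: b.reads[0] + b.reads[1]}
    for name, reads in (extra_read_sets or {}).items():
        read_sets[name] = [r if isinstance(r, str) else r[1] for r in reads]
    estimates, _tables = bootstrap_distances(
        read_sets,
        reps=cfg.bootstrap_reps,
        seed=cfg.seed,
        k=cfg.sketch_k,
        s=cfg.sketch_s,
        min_copies=cfg.sketch_min_copies,
    )
    dist_rows = [
        {
            "sample_a": pa,
            "sample_b": pb,
            "distance": est.d,
            "bootstrap_mean": est.bootstrap_mean,
            "bootstrap_se": est.bootstrap_se,
            "reps": est.reps,
        }
        for (pa, pb), est in estimates.items()
    ]
    distances = pd.DataFrame(dist_rows)

    return Report(
        sample_ids=[a.id, b.id],
        host_counts=host_counts,
        matches=matches_df,
        category_counts=category_counts,
        annotations={a.id: _annotation_frame(a, cats_a), b.id: _annotation_frame(b, cats_b)},
        abundance=abundance,
        distances=distances,
        log={
            "version": __version__,
            "seed": cfg.seed,
            "params": {
                "min_contig": cfg.min_contig,
                "min_bin": cfg.min_bin,
                "link_threshold": cfg.link_threshold,
                "pair_ani_threshold": cfg.pair_ani_threshold,
                "phage_ani_threshold": cfg.phage_ani_threshold,
                "sketch": [cfg.sketch_k, cfg.sketch_s, cfg.sketch_min_copies],
                "bootstrap_reps": cfg.bootstrap_reps,
            },
        },
    )


def write_report(report: Report, outdir) -> list[Path]:
    """Write the report as TSV tables plus a JSON bundle; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def tsv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    tsv(report.host_counts, "host_counts.tsv")
    tsv(report.matches, "matches.tsv")
    tsv(report.category_counts, "category_counts.tsv")
    for sid, df in report.annotations.items():
        tsv(df, f"annotations_{sid}.tsv")
    tsv(report.abundance, "abundance.tsv")
    tsv(report.distances, "distances.tsv")
    p = out / "report.json"
    p.write_text(report.to_json())
    written.append(p)
    return written
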
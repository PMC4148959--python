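"""Breakpoints, carriers, population frequencies, gene context, evidence.

A filtered candidate becomes a micSeq call once its insertion breakpoint is
estimated from the anchor cluster, per-sample carrier status is recomputed by
mapping each sample's orphan reads back onto the sequence (a sample carries
the micSeq when it contributes at least three mapping orphan reads), and the
overall carrier fraction clears the commonness threshold (1% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .align import SeedIndex
from .formats import BedFeature, GenomicInterval
from .merge_filter import CandidateMicSeq

__all__ = [
    "CarrierConfig",
    "MicSeqCall",
    "estimate_breakpoint",
    "map_reads_to_micseq",
    "call_carriers",
    "classify_gene_context",
    "score_evidence",
]


@dataclass(slots=True)
class CarrierConfig:
    min_reads_carrier: int = 3
    min_pop_freq: float = 0.01
    seed_len: int = 15
    map_identity: float = 0.95
    breakpoint_tolerance: int = 500  # max +/- flank disagreement for a point call


@dataclass(slots=True)
class MicSeqCall:
    id: str
    seq: str
    breakpoint: GenomicInterval
    carriers: dict[str, int] = field(default_factory=dict)  # sample -> hit count
    pop_freq: dict[str, float] = field(default_factory=dict)
    gene_context: str = "intergenic"
    evidence: dict[str, int] = field(default_factory=dict)
    candidate: Optional[CandidateMicSeq] = None


def estimate_breakpoint(cand: CandidateMicSeq, tolerance: int = 500) -> GenomicInterval:
    """Predict the insertion locus from the anchor cluster.

    Forward-strand anchors sit on the left flank of the insertion, so the
    rightmost end of the + anchors (L) approaches the breakpoint from the
    left; reverse-strand anchors sit on the right flank, so the leftmost
    start of the - anchors (R) approaches it from the right.  When both
    flanks are present and agree (L <= R + tolerance) the call is the point
    floor((L+R)/2).  With one-sided evidence the call falls back to the
    anchor-cluster span — the ~1 kb-resolution interval the anchors support.
    """
    cluster = cand.anchor_cluster
    if cluster is None:
        raise ValueError(f"{cand.id}: no anchor cluster")
    in_window = [
        r for r in cand.anchor_records
        if r.anchor_chrom == cluster.chrom
        and cluster.window_start <= r.anchor_pos < cluster.window_end
    ]
    if not in_window:
        raise ValueError(f"{cand.id}: empty anchor cluster")
    plus_ends = [r.anchor_end for r in in_window if r.anchor_strand == "+"]
    minus_starts = [r.anchor_pos for r in in_window if r.anchor_strand == "-"]
    if plus_ends and minus_starts:
        L, R = max(plus_ends), min(minus_starts)
        if L <= R + tolerance:
            p = (L + R) // 2
            return GenomicInterval(cluster.chrom, p, p)
    span_lo = min(r.anchor_pos for r in in_window)
    span_hi = max(r.anchor_end for r in in_window)
    return GenomicInterval(cluster.chrom, span_lo, span_hi)


def map_reads_to_micseq(
    reads: Sequence[str],
    micseq_seq: str,
    cfg: CarrierConfig = CarrierConfig(),
    index: Optional[SeedIndex] = None,
) -> tuple[list[bool], np.ndarray]:
    """Map reads onto a micSeq by exact seed + ungapped extension.

    A read hits when it shares an exact ``seed_len``-mer with the micSeq on
    either strand and the seeded diagonal reaches >= cfg.map_identity identity
    over the overlap.  Returns per-read hit booleans and the per-base coverage
    vector over the micSeq.
    """
    if len(micseq_seq) < cfg.seed_len:
        raise ValueError("micSeq shorter than the seed length")
    idx = index if index is not None else SeedIndex(micseq_seq, cfg.seed_len)
    hits: list[bool] = []
    coverage = np.zeros(len(micseq_seq), dtype=np.int64)
    for read in reads:
        placement = idx.ungapped_hit(read, cfg.map_identity)
        if placement is None:
            hits.append(False)
            continue
        _, s0, s1, _ = placement
        coverage[s0:s1] += 1
        hits.append(True)
    return hits, coverage


def call_carriers(
    micseq_seq: str,
    per_sample_orphans: Mapping[str, tuple[str, Sequence[str]]],
    cfg: CarrierConfig = CarrierConfig(),
) -> tuple[dict[str, int], dict[str, float], float]:
    """Carrier status per sample and carrier frequency per population.

    ``per_sample_orphans`` maps sample_id -> (population, orphan read
    sequences).  A sample is a carrier iff >= cfg.min_reads_carrier of its
    orphan reads map onto the micSeq.  Returns (per-sample mapped-read
    counts, per-population carrier fractions, overall carrier fraction).
    """
    idx = SeedIndex(micseq_seq, cfg.seed_len)
    counts: dict[str, int] = {}
    pop_sizes: dict[str, int] = {}
    pop_carriers: dict[str, int] = {}
    n_carriers = 0
    for sample_id in sorted(per_sample_orphans):
        population, reads = per_sample_orphans[sample_id]
        hits, _ = map_reads_to_micseq(reads, micseq_seq, cfg, index=idx)
        c = int(sum(hits))
        counts[sample_id] = c
        pop_sizes[population] = pop_sizes.get(population, 0) + 1
        if c >= cfg.min_reads_carrier:
            pop_carriers[population] = pop_carriers.get(population, 0) + 1
            n_carriers += 1
    pop_freq = {p: pop_carriers.get(p, 0) / n for p, n in sorted(pop_sizes.items())}
    overall = n_carriers / len(per_sample_orphans) if per_sample_orphans else 0.0
    return counts, pop_freq, overall


_PRECEDENCE = ("exon", "utr", "intron")


def classify_gene_context(
    breakpoint: GenomicInterval,
    annotation: Iterable[BedFeature],
    flank: int = 5000,
) -> str:
    """Most specific feature overlapping the breakpoint, else flank, else intergenic.

    Precedence: exon > utr > intron.  ``flank_5kb`` means within ``flank`` nt
    of a gene-typed interval without overlapping any typed feature.
    """
    overlapping: set[str] = set()
    near_gene = False
    for feat in annotation:
        if feat.interval.chrom != breakpoint.chrom:
            continue
        if feat.interval.overlaps(breakpoint):
            overlapping.add(feat.feature_type)
        elif feat.feature_type == "gene":
            gap = max(
                feat.interval.start - max(breakpoint.end, breakpoint.start + 1),
                breakpoint.start - feat.interval.end,
            )
            if gap < flank:
                near_gene = True
    for ftype in _PRECEDENCE:
        if ftype in overlapping:
            return ftype
    if "gene" in overlapping:
        return "intron"  # inside a gene body without finer typing
    return "flank_5kb" if near_gene else "intergenic"


def score_evidence(
    micseqs: Mapping[str, str],
    evidence_reads: Mapping[str, Sequence[str]],
    control_reads: Optional[Mapping[str, Sequence[str]]] = None,
    expressed_threshold: int = 100,
    cfg: CarrierConfig = CarrierConfig(),
) -> dict[str, dict]:
    """Count evidence reads (RNA-seq / ChIP-seq) mapping to each micSeq.

    Per micSeq: mapped read count per dataset, a flagged verdict when any
    single dataset exceeds ``expressed_threshold`` reads, and — when control
    datasets are supplied — treatment vs control mean counts side by side.
    """
    out: dict[str, dict] = {}
    for mid, seq in sorted(micseqs.items()):
        idx = SeedIndex(seq, cfg.seed_len)
        per_ds = {}
        for ds, reads in sorted(evidence_reads.items()):
            hits, _ = map_reads_to_micseq(reads, seq, cfg, index=idx)
            per_ds[ds] = int(sum(hits))
        entry: dict = {
            "counts": per_ds,
            "flagged": any(c > expressed_threshold for c in per_ds.values()),
        }
        if control_reads is not None:
            ctrl = {}
            for ds, reads in sorted(control_reads.items()):
                hits, _ = map_reads_to_micseq(reads, seq, cfg, index=idx)
                ctrl[ds] = int(sum(hits))
            entry["control_counts"] = ctrl
            entry["treatment_mean"] = float(np.mean(list(per_ds.values()))) if per_ds else 0.0
            entry["control_mean"] = float(np.mean(list(ctrl.values()))) if ctrl else 0.0
        out[mid] = entry
    return out
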
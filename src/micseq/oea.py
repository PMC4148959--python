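"""Pair classification and one-end-anchor (OEA) pooling.

A pair is OEA when exactly one mate maps uniquely to the reference (the
anchor) and the other does not (the orphan).  Orphans are pooled across all
samples, binned by the anchor's chromosome, so that sequences common in the
population accumulate enough coverage to assemble even from shallow
(~4x) per-individual data.  Unique mapping is operationalized as
MAPQ >= ``min_mapq`` (default 20).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .dnautil import revcomp
from .formats import AlignmentRecord, ReadPair

__all__ = [
    "PairClass",
    "OeaRecord",
    "classify_pair",
    "pool_oea",
    "orient_orphan",
    "estimate_insert_range",
    "PoolResult",
]


class PairClass(enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT_BOTH_MAPPED = "discordant_both_mapped"
    OEA = "oea"
    FULL_ORPHAN = "full_orphan"


@dataclass(slots=True)
class OeaRecord:
    """One orphan read tied to its anchor's placement and sample provenance."""

    orphan_seq: str
    orphan_qual: np.ndarray
    anchor_chrom: str
    anchor_pos: int  # 0-based leftmost of the anchor read
    anchor_end: int  # anchor_pos + anchor read length
    anchor_strand: str  # "+" or "-"
    sample_id: str
    population: str
    pair_id: str


def classify_pair(
    a1: AlignmentRecord,
    a2: AlignmentRecord,
    min_mapq: int = 20,
    insert_range: Optional[tuple[float, float]] = None,
) -> PairClass:
    """Assign exactly one class to a pair of alignment records.

    Exactly one mate mapped with MAPQ >= min_mapq -> OEA; a sole mapped mate
    below min_mapq is not a trustworthy anchor, demoting the pair to
    FULL_ORPHAN.  Both mapped in FR orientation on one chromosome within
    ``insert_range`` (distance between leftmost positions; no range check when
    None) -> CONCORDANT; any other both-mapped geometry -> DISCORDANT.
    """
    if a1.mate_index == a2.mate_index:
        raise ValueError(f"pair {a1.pair_id!r}: both records claim mate {a1.mate_index}")
    if not a1.mapped and not a2.mapped:
        return PairClass.FULL_ORPHAN
    if a1.mapped != a2.mapped:
        anchor = a1 if a1.mapped else a2
        if (anchor.mapq or 0) >= min_mapq:
            return PairClass.OEA
        return PairClass.FULL_ORPHAN
    # both mapped
    if a1.chrom != a2.chrom or a1.strand == a2.strand:
        return PairClass.DISCORDANT_BOTH_MAPPED
    fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
    if fwd.pos > rev.pos:  # forward mate must be leftmost (FR orientation)
        return PairClass.DISCORDANT_BOTH_MAPPED
    if insert_range is not None:
        lo, hi = insert_range
        if not (lo <= rev.pos - fwd.pos <= hi):
            return PairClass.DISCORDANT_BOTH_MAPPED
    return PairClass.CONCORDANT


def estimate_insert_range(
    distances: Iterable[float], n_sd: float = 4.0
) -> tuple[float, float]:
    """mean +/- n_sd * sd of observed concordant leftmost-position distances."""
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances supplied")
    mu, sd = float(d.mean()), float(d.std())
    return max(0.0, mu - n_sd * sd), mu + n_sd * sd


@dataclass(slots=True)
class PoolResult:
    """OEA records binned by anchor chromosome plus bookkeeping counts."""

    by_chrom: dict[str, list[OeaRecord]] = field(default_factory=dict)
    class_counts: dict[PairClass, int] = field(
        default_factory=lambda: {c: 0 for c in PairClass}
    )
    full_orphans: list[ReadPair] = field(default_factory=list)
    pairs_in: int = 0
    samples: dict[str, str] = field(default_factory=dict)  # sample_id -> population


def pool_oea(
    streams: Iterable[Iterable[tuple[ReadPair, AlignmentRecord, AlignmentRecord]]],
    min_mapq: int = 20,
    insert_range: Optional[tuple[float, float]] = None,
    known_chroms: Optional[set[str]] = None,
    keep_full_orphans: bool = False,
) -> PoolResult:
    """Classify every pair of every per-sample stream and pool OEA orphans.

    ``streams`` yields per-sample iterables of (ReadPair, mate1 alignment,
    mate2 alignment); sample and population tags travel on the ReadPair.
    Records are binned by anchor chromosome and sorted by anchor position
    within each bin.
    """
    res = PoolResult()
    for stream in streams:
        for pair, a1, a2 in stream:
            res.pairs_in += 1
            if pair.sample_id:
                res.samples.setdefault(pair.sample_id, pair.population)
            cls = classify_pair(a1, a2, min_mapq=min_mapq, insert_range=insert_range)
            res.class_counts[cls] += 1
            if cls is PairClass.FULL_ORPHAN and keep_full_orphans:
                res.full_orphans.append(pair)
            if cls is not PairClass.OEA:
                continue
            anchor, orphan_idx = (a1, 2) if a1.mapped else (a2, 1)
            if known_chroms is not None and anchor.chrom not in known_chroms:
                raise ValueError(
                    f"pair {pair.pair_id!r}: anchor chromosome {anchor.chrom!r} "
                    "not present in the reference"
                )
            if orphan_idx == 1:
                orphan_seq, orphan_qual = pair.mate1_seq, pair.mate1_qual
                anchor_len = len(pair.mate2_seq)
            else:
                orphan_seq, orphan_qual = pair.mate2_seq, pair.mate2_qual
                anchor_len = len(pair.mate1_seq)
            rec = OeaRecord(
                orphan_seq=orphan_seq,
                orphan_qual=orphan_qual,
                anchor_chrom=anchor.chrom,
                anchor_pos=anchor.pos,
                anchor_end=anchor.pos + anchor_len,
                anchor_strand=anchor.strand,
                sample_id=pair.sample_id,
                population=pair.population,
                pair_id=pair.pair_id,
            )
            res.by_chrom.setdefault(anchor.chrom, []).append(rec)
    for recs in res.by_chrom.values():
        recs.sort(key=lambda r: (r.anchor_pos, r.pair_id))
    return res


def orient_orphan(rec: OeaRecord) -> str:
    """Orphan sequence flipped onto the inserted sequence's forward sense.

    A forward-strand anchor's mate was sequenced on the reverse strand of the
    fragment, so it is reverse-complemented; a reverse-strand anchor's mate is
    returned as stored.
    """
    if rec.anchor_strand == "+":
        return revcomp(rec.orphan_seq)
    return rec.orphan_seq
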
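"""Synthetic diploid cohorts with non-reference insertions, reads and truth.

The generator emulates the study design the pipeline targets: a population of
diploid individuals sequenced shallowly (~4x) with Illumina-like paired-end
reads, a subset of whom carry each of several insertions that are absent from
the reference.  Reads are drawn per haplotype with a Normal insert-size
distribution (FR orientation), i.i.d. substitution errors, and constant
qualities matching the error rate.  Alignments are emitted by an *ideal
aligner*: a read maps iff at least 95% of its bases derive from reference
sequence, at its reference projection — so pairs straddling an insertion
boundary become one-end-anchored and pairs inside a long insertion become
full orphans, isolating the pipeline's own computation from real-aligner
behavior.

Everything is reproducible bit-for-bit from (config, seed): each individual
draws from ``default_rng((seed, individual_index))``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .dnautil import CODE_TO_BASE, decode, dust_fraction
from .formats import AlignmentRecord, ReadPair, write_fasta

__all__ = [
    "InsertionSpec",
    "SimConfig",
    "Individual",
    "SimTruth",
    "Population",
    "make_population",
    "simulate_individual",
    "pair_stream",
    "write_cohort",
]

_COMP_CODES = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


@dataclass(slots=True)
class InsertionSpec:
    """One non-reference insertion to plant in the simulated population."""

    length: int
    freq: float  # target allele frequency among eligible individuals
    chrom: Optional[str] = None  # None -> first chromosome
    locus: Optional[int] = None  # None -> assigned evenly along the chromosome
    populations: Optional[tuple[str, ...]] = None  # None -> shared by all

    def __post_init__(self):
        if not 0.0 < self.freq <= 1.0:
            raise ValueError("insertion frequency must be in (0, 1]")
        if self.length < 1:
            raise ValueError("insertion length must be positive")


@dataclass(slots=True)
class SimConfig:
    ref_len: int = 100_000
    n_chroms: int = 1
    n_individuals: dict[str, int] = field(default_factory=lambda: {"AFR": 10})
    insertions: list[InsertionSpec] = field(default_factory=list)
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 4.0  # total bases per individual / ref_len
    base_error_rate: float = 0.002
    seed: int = 0
    map_ref_frac: float = 0.95  # ideal-aligner mapping rule
    mapq: int = 60
    min_locus_gap: int = 10_000

    @property
    def quality(self) -> int:
        if self.base_error_rate <= 0:
            return 40
        return max(2, round(-10 * math.log10(self.base_error_rate)))


@dataclass(slots=True)
class Individual:
    sample_id: str
    population: str
    # per insertion: (hap0 carries, hap1 carries)
    haplotypes: list[tuple[bool, bool]]

    def genotype(self, ins_idx: int) -> int:
        h = self.haplotypes[ins_idx]
        return int(h[0]) + int(h[1])


@dataclass(slots=True)
class TruthInsertion:
    chrom: str
    locus: int  # 0-based reference point of insertion
    seq: str
    freq_target: float
    populations: Optional[tuple[str, ...]]
    genotypes: dict[str, int] = field(default_factory=dict)

    @property
    def realized_allele_freq(self) -> float:
        n = len(self.genotypes)
        return sum(self.genotypes.values()) / (2 * n) if n else 0.0


@dataclass(slots=True)
class SimTruth:
    insertions: list[TruthInsertion]
    # filled per individual by simulate_individual: sample -> class counts
    pair_classes: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass(slots=True)
class Population:
    cfg: SimConfig
    reference: dict[str, str]
    ref_codes: dict[str, np.ndarray]
    individuals: list[Individual]
    truth: SimTruth


def _assign_loci(cfg: SimConfig) -> list[tuple[str, int]]:
    """Resolve (chrom, locus) for every insertion; validate spacing."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    placed: list[tuple[str, int]] = []
    auto = [i for i, ins in enumerate(cfg.insertions) if ins.locus is None]
    loci: list[Optional[tuple[str, int]]] = [
        (ins.chrom or chroms[0], ins.locus) if ins.locus is not None else None
        for ins in cfg.insertions
    ]
    if auto:
        # spread evenly along the first chromosome, away from the edges
        n = len(auto)
        step = cfg.ref_len // (n + 1)
        for rank, i in enumerate(auto, start=1):
            loci[i] = (cfg.insertions[i].chrom or chroms[0], rank * step)
    by_chrom: dict[str, list[int]] = {}
    for i, pair in enumerate(loci):
        chrom, pos = pair
        if not 0 < pos < cfg.ref_len:
            raise ValueError(f"insertion {i} locus {pos} outside the reference")
        by_chrom.setdefault(chrom, []).append(pos)
        placed.append((chrom, pos))
    for chrom, positions in by_chrom.items():
        positions = sorted(positions)
        for a, b in zip(positions, positions[1:]):
            if b - a < cfg.min_locus_gap:
                raise ValueError(
                    f"insertion loci {a} and {b} on {chrom} closer than {cfg.min_locus_gap} nt"
                )
    return placed


def _random_insertion_seq(rng: np.random.Generator, length: int, reference: dict[str, str]) -> str:
    """Random insertion sequence, complexity-normal and novel vs the reference."""
    for _ in range(100):
        seq = decode(rng.integers(0, 4, size=length, dtype=np.uint8))
        if dust_fraction(seq) > 0.5:
            continue
        probe = 20
        if any(seq[i : i + probe] in ref for ref in reference.values()
               for i in range(0, length - probe + 1, 10)):
            continue
        return seq
    raise RuntimeError("could not draw an acceptable insertion sequence")


def make_population(cfg: SimConfig) -> Population:
    """Draw the reference, the insertion set and every individual's genotypes."""
    rng = np.random.default_rng((cfg.seed, 0))
    reference: dict[str, str] = {}
    ref_codes: dict[str, np.ndarray] = {}
    for i in range(cfg.n_chroms):
        codes = rng.integers(0, 4, size=cfg.ref_len, dtype=np.uint8)
        chrom = f"chr{i + 1}"
        ref_codes[chrom] = codes
        reference[chrom] = decode(codes)
    loci = _assign_loci(cfg)
    truths = []
    for ins, (chrom, pos) in zip(cfg.insertions, loci):
        truths.append(
            TruthInsertion(
                chrom=chrom,
                locus=pos,
                seq=_random_insertion_seq(rng, ins.length, reference),
                freq_target=ins.freq,
                populations=ins.populations,
            )
        )
    individuals = []
    for pop_name in sorted(cfg.n_individuals):
        for j in range(cfg.n_individuals[pop_name]):
            haps = []
            for ins, truth in zip(cfg.insertions, truths):
                eligible = ins.populations is None or pop_name in ins.populations
                if eligible:
                    h = (bool(rng.random() < ins.freq), bool(rng.random() < ins.freq))
                else:
                    h = (False, False)
                haps.append(h)
            ind = Individual(sample_id=f"{pop_name}{j:03d}", population=pop_name, haplotypes=haps)
            for k, truth in enumerate(truths):
                truth.genotypes[ind.sample_id] = ind.genotype(k)
            individuals.append(ind)
    return Population(
        cfg=cfg,
        reference=reference,
        ref_codes=ref_codes,
        individuals=individuals,
        truth=SimTruth(insertions=truths),
    )


@dataclass(slots=True)
class IndividualReads:
    """All fragments of one individual, as arrays (one block per chrom+hap)."""

    sample_id: str
    population: str
    chrom: str
    mate1: np.ndarray  # (n, read_len) uint8 codes, forward sense
    mate2: np.ndarray  # (n, read_len) uint8 codes, as sequenced (RC of fragment end)
    mapped1: np.ndarray
    mapped2: np.ndarray
    pos1: np.ndarray
    pos2: np.ndarray
    pair_ids: list[str]


def _hap_segments(
    cfg: SimConfig, chrom: str, ref_codes: np.ndarray, carried: list[TruthInsertion]
):
    """Haplotype code array plus segment tables for reference projection.

    Segments alternate reference / insertion.  Arrays: seg_start (haplotype
    coordinate), seg_end, is_ref, ref_start (reference coordinate of the
    segment start; for an insertion segment, of the *next* reference base).
    """
    carried = sorted(carried, key=lambda t: t.locus)
    parts = []
    seg_start, seg_end, is_ref, ref_start = [], [], [], []
    hap_pos = 0
    ref_pos = 0
    from .dnautil import encode

    for t in carried:
        if t.locus > ref_pos:
            seg = ref_codes[ref_pos : t.locus]
            parts.append(seg)
            seg_start.append(hap_pos); seg_end.append(hap_pos + len(seg))
            is_ref.append(True); ref_start.append(ref_pos)
            hap_pos += len(seg)
            ref_pos = t.locus
        ins_codes = encode(t.seq)
        parts.append(ins_codes)
        seg_start.append(hap_pos); seg_end.append(hap_pos + len(ins_codes))
        is_ref.append(False); ref_start.append(ref_pos)  # next ref base
        hap_pos += len(ins_codes)
    tail = ref_codes[ref_pos:]
    parts.append(tail)
    seg_start.append(hap_pos); seg_end.append(hap_pos + len(tail))
    is_ref.append(True); ref_start.append(ref_pos)
    hap = np.concatenate(parts) if len(parts) > 1 else parts[0]
    return (
        hap,
        np.asarray(seg_start), np.asarray(seg_end),
        np.asarray(is_ref), np.asarray(ref_start),
    )


def simulate_individual(pop: Population, index: int) -> list[IndividualReads]:
    """Draw one individual's read pairs and their ideal alignments.

    Deterministic given (cfg.seed, index).  Returns one block per
    (chromosome, haplotype) with reads already error-mutated and truth
    mapping fields computed from the pre-error fragment coordinates.
    """
    cfg = pop.cfg
    ind = pop.individuals[index]
    rng = np.random.default_rng((cfg.seed, 1 + index))
    rl = cfg.read_len
    blocks = []
    class_counts = {"concordant": 0, "oea": 0, "full_orphan": 0}
    for chrom in sorted(pop.ref_codes):
        for hap_idx in (0, 1):
            carried = [
                t for k, t in enumerate(pop.truth.insertions)
                if t.chrom == chrom and ind.haplotypes[k][hap_idx]
            ]
            hap, seg_start, seg_end, is_ref, ref_start = _hap_segments(
                cfg, chrom, pop.ref_codes[chrom], carried
            )
            hap_len = len(hap)
            n_pairs = int(round((cfg.coverage / 2.0) * hap_len / (2.0 * rl)))
            if n_pairs == 0:
                continue
            ins_sizes = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)
            ins_sizes = np.clip(np.rint(ins_sizes), 2 * rl, hap_len).astype(np.int64)
            starts = (rng.random(n_pairs) * (hap_len - ins_sizes + 1)).astype(np.int64)
            m1 = hap[starts[:, None] + np.arange(rl)]
            ends2 = starts + ins_sizes  # exclusive haplotype end of the fragment
            m2_fwd = hap[(ends2 - rl)[:, None] + np.arange(rl)]
            m2 = _COMP_CODES[m2_fwd[:, ::-1]]
            if cfg.base_error_rate > 0:
                for mat in (m1, m2):
                    mask = rng.random(mat.shape) < cfg.base_error_rate
                    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
                    mat[mask] = (mat[mask] + shift) % 4
            map1, p1 = _project(starts, starts + rl, seg_start, seg_end, is_ref, ref_start, cfg)
            map2, p2 = _project(ends2 - rl, ends2, seg_start, seg_end, is_ref, ref_start, cfg)
            both = map1 & map2
            neither = ~map1 & ~map2
            class_counts["concordant"] += int(both.sum())
            class_counts["full_orphan"] += int(neither.sum())
            class_counts["oea"] += int((~both & ~neither).sum())
            pair_ids = [
                f"{ind.sample_id}:{chrom}:h{hap_idx}:{i}" for i in range(n_pairs)
            ]
            blocks.append(
                IndividualReads(
                    sample_id=ind.sample_id,
                    population=ind.population,
                    chrom=chrom,
                    mate1=m1, mate2=m2,
                    mapped1=map1, mapped2=map2,
                    pos1=p1, pos2=p2,
                    pair_ids=pair_ids,
                )
            )
    pop.truth.pair_classes[ind.sample_id] = class_counts
    return blocks


def _project(s, e, seg_start, seg_end, is_ref, ref_start, cfg: SimConfig):
    """Vectorized ideal-aligner rule for reads spanning at most one boundary.

    Works because insertions are longer than a read and reference segments
    are many kilobases, so a read overlaps at most two segments.
    """
    idx = np.searchsorted(seg_start, s, side="right") - 1
    first_end = seg_end[idx]
    in_ref = is_ref[idx]
    ref_bases = np.where(
        in_ref,
        np.minimum(e, first_end) - s,
        np.maximum(0, e - first_end),
    )
    frac = ref_bases / (e - s)
    mapped = frac >= cfg.map_ref_frac
    nxt = np.minimum(idx + 1, len(seg_start) - 1)
    pos = np.where(in_ref, ref_start[idx] + (s - seg_start[idx]), ref_start[nxt])
    return mapped, pos


def pair_stream(
    pop: Population, index: int
) -> Iterator[tuple[ReadPair, AlignmentRecord, AlignmentRecord]]:
    """One individual's (ReadPair, mate1 alignment, mate2 alignment) stream."""
    cfg = pop.cfg
    q = np.full(cfg.read_len, cfg.quality, dtype=np.int16)
    for blk in simulate_individual(pop, index):
        m1s = CODE_TO_BASE[blk.mate1]
        m2s = CODE_TO_BASE[blk.mate2]
        for i, pid in enumerate(blk.pair_ids):
            pair = ReadPair(
                pair_id=pid,
                mate1_seq=m1s[i].tobytes().decode("ascii"),
                mate1_qual=q,
                mate2_seq=m2s[i].tobytes().decode("ascii"),
                mate2_qual=q,
                sample_id=blk.sample_id,
                population=blk.population,
            )
            if blk.mapped1[i]:
                a1 = AlignmentRecord(pid, 1, True, blk.chrom, int(blk.pos1[i]), "+", cfg.mapq)
            else:
                a1 = AlignmentRecord(pid, 1, False)
            if blk.mapped2[i]:
                a2 = AlignmentRecord(pid, 2, True, blk.chrom, int(blk.pos2[i]), "-", cfg.mapq)
            else:
                a2 = AlignmentRecord(pid, 2, False)
            yield pair, a1, a2


def write_cohort(pop: Population, outdir) -> None:
    """Write ref.fa, per-sample FASTQ pairs and SAM files, and truth.json."""
    import os

    import pysam

    os.makedirs(outdir, exist_ok=True)
    cfg = pop.cfg
    write_fasta(sorted(pop.reference.items()), os.path.join(outdir, "ref.fa"))
    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [
            {"SN": c, "LN": len(pop.reference[c])} for c in sorted(pop.reference)
        ],
    }
    chrom_ids = {c: i for i, c in enumerate(sorted(pop.reference))}
    qual_str = pysam.qualities_to_qualitystring([cfg.quality] * cfg.read_len)
    for index, ind in enumerate(pop.individuals):
        fq1 = open(os.path.join(outdir, f"{ind.sample_id}_1.fastq"), "w")
        fq2 = open(os.path.join(outdir, f"{ind.sample_id}_2.fastq"), "w")
        sam = pysam.AlignmentFile(
            os.path.join(outdir, f"{ind.sample_id}.sam"), "wh", header=header
        )
        for pair, a1, a2 in pair_stream(pop, index):
            q = qual_str
            fq1.write(f"@{pair.pair_id}/1\n{pair.mate1_seq}\n+\n{q}\n")
            fq2.write(f"@{pair.pair_id}/2\n{pair.mate2_seq}\n+\n{q}\n")
            for rec, mate_rec, seq, first in (
                (a1, a2, pair.mate1_seq, True),
                (a2, a1, pair.mate2_seq, False),
            ):
                a = pysam.AlignedSegment(sam.header)
                a.query_name = pair.pair_id
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(q)
                flag = 0x1 | (0x40 if first else 0x80)
                if rec.mapped:
                    if rec.strand == "-":
                        flag |= 0x10
                else:
                    flag |= 0x4
                if not mate_rec.mapped:
                    flag |= 0x8
                elif mate_rec.strand == "-":
                    flag |= 0x20
                a.flag = flag
                if rec.mapped:
                    a.reference_id = chrom_ids[rec.chrom]
                    a.reference_start = rec.pos
                    a.mapping_quality = rec.mapq
                    a.cigarstring = f"{len(seq)}M"
                sam.write(a)
        fq1.close(); fq2.close(); sam.close()
    manifest = {
        "seed": cfg.seed,
        "samples": [
            {"sample_id": i.sample_id, "population": i.population}
            for i in pop.individuals
        ],
        "insertions": [
            {
                "chrom": t.chrom,
                "locus": t.locus,
                "length": len(t.seq),
                "seq": t.seq,
                "freq_target": t.freq_target,
                "realized_allele_freq": t.realized_allele_freq,
                "genotypes": t.genotypes,
            }
            for t in pop.truth.insertions
        ],
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
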
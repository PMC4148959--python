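"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion to and from
1-based SAM/annotation conventions happens only in this module, at the file
boundary.  FASTQ qualities are Phred+33 and are held in memory as numpy int
arrays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadPair",
    "AlignmentRecord",
    "GenomicInterval",
    "BedFeature",
    "FormatError",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_alignments",
    "read_fasta",
    "write_fasta",
    "read_bed",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(slots=True)
class ReadPair:
    """A mate pair with per-base Phred qualities and sample provenance."""

    pair_id: str
    mate1_seq: str
    mate1_qual: np.ndarray
    mate2_seq: str
    mate2_qual: np.ndarray
    sample_id: str = ""
    population: str = ""

    def validate(self) -> None:
        for seq, qual in ((self.mate1_seq, self.mate1_qual), (self.mate2_seq, self.mate2_qual)):
            if len(seq) != len(qual):
                raise FormatError(f"{self.pair_id}: sequence/quality length mismatch")
            if set(seq) - set("ACGTN"):
                raise FormatError(f"{self.pair_id}: non-ACGTN characters in sequence")


@dataclass(slots=True)
class AlignmentRecord:
    """One mate's alignment; unmapped records carry null placement fields."""

    pair_id: str
    mate_index: int  # 1 or 2
    mapped: bool
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 0-based leftmost on forward strand
    strand: Optional[str] = None  # "+" or "-"
    mapq: Optional[int] = None


@dataclass(slots=True, frozen=True)
class GenomicInterval:
    """0-based half-open interval; ``start == end`` denotes a point."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        if self.chrom != other.chrom:
            return False
        # points participate in overlap as 1-wide
        s1, e1 = self.start, max(self.end, self.start + 1)
        s2, e2 = other.start, max(other.end, other.start + 1)
        return s1 < e2 and s2 < e1


@dataclass(slots=True)
class BedFeature:
    interval: GenomicInterval
    name: str
    feature_type: str  # exon | utr | intron | gene


def read_fastq_pairs(
    path1, path2, sample_id: str = "", population: str = ""
) -> Iterator[ReadPair]:
    """Stream mate pairs from two record-synchronized FASTQ files.

    Raises :class:`FormatError` naming the first divergent record if the files
    hold different numbers of records.
    """
    with open(path1) as h1, open(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        sentinel = object()
        for idx, (r1, r2) in enumerate(
            itertools.zip_longest(it1, it2, fillvalue=sentinel), start=1
        ):
            if r1 is sentinel or r2 is sentinel:
                short = path2 if r2 is sentinel else path1
                raise FormatError(
                    f"mate files out of sync: {short} ends before record {idx}"
                )
            (id1, seq1, q1), (id2, seq2, q2) = r1, r2
            pair_id = id1.split()[0].removesuffix("/1").removesuffix("/2")
            yield ReadPair(
                pair_id=pair_id,
                mate1_seq=seq1.upper(),
                mate1_qual=_decode_qual(q1),
                mate2_seq=seq2.upper(),
                mate2_qual=_decode_qual(q2),
                sample_id=sample_id,
                population=population,
            )


def _decode_qual(qual_str: str) -> np.ndarray:
    return (np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33)


def _encode_qual(qual: np.ndarray) -> str:
    return (np.asarray(qual, dtype=np.int16).clip(0, 93) + 33).astype(np.uint8).tobytes().decode("ascii")


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> int:
    """Write pairs to two synchronized FASTQ files; returns the pair count."""
    n = 0
    with open(path1, "w") as h1, open(path2, "w") as h2:
        for p in pairs:
            h1.write(f"@{p.pair_id}/1\n{p.mate1_seq}\n+\n{_encode_qual(p.mate1_qual)}\n")
            h2.write(f"@{p.pair_id}/2\n{p.mate2_seq}\n+\n{_encode_qual(p.mate2_qual)}\n")
            n += 1
    return n


def read_alignments(path) -> Iterator[tuple[str, AlignmentRecord, AlignmentRecord]]:
    """Stream (pair_id, mate1 record, mate2 record) from a name-grouped SAM/BAM.

    SAM 1-based positions become internal 0-based; secondary and supplementary
    records are skipped; FLAG 0x4 wins over any placement fields.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise FormatError(f"{path}: missing sequence dictionary (@SQ header lines)")
        pending: dict[int, AlignmentRecord] = {}
        pending_name: Optional[str] = None
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            name = aln.query_name
            if pending_name is not None and name != pending_name:
                raise FormatError(
                    f"{path}: orphaned record for pair {pending_name!r} "
                    "(file must be name-grouped with both mates adjacent)"
                )
            rec = _to_record(aln, fh)
            mate = 1 if aln.is_read1 or not aln.is_read2 else 2
            if mate in pending:
                raise FormatError(f"{path}: two records claim mate {mate} of {name!r}")
            pending[mate] = rec
            pending_name = name
            if len(pending) == 2:
                yield name, pending[1], pending[2]
                pending, pending_name = {}, None
        if pending:
            raise FormatError(f"{path}: orphaned record for pair {pending_name!r} at EOF")


def _to_record(aln, fh) -> AlignmentRecord:
    mate = 1 if aln.is_read1 or not aln.is_read2 else 2
    if aln.is_unmapped:
        return AlignmentRecord(aln.query_name, mate, mapped=False)
    return AlignmentRecord(
        aln.query_name,
        mate,
        mapped=True,
        chrom=fh.get_reference_name(aln.reference_id),
        pos=aln.reference_start,  # pysam is already 0-based
        strand="-" if aln.is_reverse else "+",
        mapq=aln.mapping_quality,
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into a list of (id, sequence) tuples."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> int:
    """Write (id, sequence) records as 60-column wrapped FASTA.

    Raises :class:`FormatError` on duplicate ids.
    """
    seen: set[str] = set()
    n = 0
    with open(path, "w") as fh:
        for rid, seq in records:
            if rid in seen:
                raise FormatError(f"duplicate FASTA id {rid!r}")
            seen.add(rid)
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


_FEATURE_TYPES = {"exon", "utr", "intron", "gene"}


def read_bed(path) -> list[BedFeature]:
    """Read gene annotation from a BED file with a feature-type column.

    Columns: chrom, start, end, name, score, strand, feature_type — where
    feature_type is one of exon/utr/intron/gene.  BED is already 0-based
    half-open, so coordinates pass through untouched.
    """
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise FormatError(f"{path}:{lineno}: expected >=7 BED columns, got {len(cols)}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            ftype = cols[6].lower()
            if ftype not in _FEATURE_TYPES:
                raise FormatError(f"{path}:{lineno}: unknown feature type {cols[6]!r}")
            strand = cols[5] if cols[5] in "+-" else None
            feats.append(
                BedFeature(GenomicInterval(cols[0], start, end, strand), cols[3], ftype)
            )
    return feats
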
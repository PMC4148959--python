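"""Multi-k de Bruijn assembly of pooled orphan reads with coverage cutoffs.

The assembler is deliberately small: nodes are (k-1)-mers, edges are k-mers
counted double-strandedly (a k-mer and its reverse complement are one edge),
unitigs are maximal unbranched paths.  The mean k-mer coverage cutoff
(default 50x) is the population-commonness filter: only sequences carried by
enough pooled individuals accumulate 50 observations of each k-mer.  Tips
(dead-end unitigs shorter than 2k with mean multiplicity below cutoff/4) are
clipped before thresholding.  Repeat resolution, bubble popping and
scaffolding are intentionally absent — orphan pools at desk scale are tiny
and candidates are reconciled downstream in the similarity graph.

Assembly is fully deterministic: traversal seeds are visited in lexicographic
order of canonical k-mers and emitted unitigs are orientation-voted by the
input reads, so identical read multisets give identical output regardless of
read order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .dnautil import BASES, revcomp

__all__ = [
    "AssemblyConfig",
    "Contig",
    "build_dbg",
    "assemble_k",
    "assemble_multik",
    "rescue_assemble",
]

DEFAULT_K_VALUES = (19, 23, 27, 31, 35, 39, 43, 47, 51, 55, 59)


@dataclass(slots=True)
class AssemblyConfig:
    k_values: tuple[int, ...] = DEFAULT_K_VALUES
    cov_cutoff: float = 50.0
    rescue_cov_cutoff: float = 20.0
    min_contig_len: int = 100

    def __post_init__(self):
        for k in self.k_values:
            if k < 3 or k % 2 == 0:
                raise ValueError(f"k values must be odd and >= 3, got {k}")
        if not self.cov_cutoff > self.rescue_cov_cutoff > 0:
            raise ValueError("require cov_cutoff > rescue_cov_cutoff > 0")


@dataclass(slots=True)
class Contig:
    seq: str
    k: int
    mean_kmer_cov: float
    read_support: dict[str, int] = field(default_factory=dict)
    id: str = ""


def count_kmers(reads: Sequence[str], k: int) -> dict[str, int]:
    """Canonical (double-stranded) k-mer multiplicities over all reads.

    k-mers containing N are skipped.  The reverse complement of each window is
    taken by slicing a single reverse-complemented copy of the read, which
    keeps counting linear.
    """
    raw: dict[str, int] = {}
    raw_get = raw.get
    for read in reads:
        n = len(read)
        if n < k:
            continue
        if "N" in read:
            for i in range(n - k + 1):
                km = read[i : i + k]
                if "N" not in km:
                    raw[km] = raw_get(km, 0) + 1
        else:
            for i in range(n - k + 1):
                km = read[i : i + k]
                raw[km] = raw_get(km, 0) + 1
    # fold forward counts onto canonical representatives (distinct k-mers are
    # far fewer than occurrences, so canonicalizing once per k-mer is cheap)
    counts: dict[str, int] = {}
    for km, c in raw.items():
        rc = revcomp(km)
        canon = km if km <= rc else rc
        counts[canon] = counts.get(canon, 0) + c
    return counts


class DeBruijnGraph:
    """Canonical k-mer count table with oriented-walk helpers."""

    def __init__(self, counts: dict[str, int], k: int):
        self.counts = counts
        self.k = k

    def count(self, kmer: str) -> int:
        rc = revcomp(kmer)
        return self.counts.get(kmer if kmer <= rc else rc, 0)

    def has(self, kmer: str) -> bool:
        return self.count(kmer) > 0

    def out_bases(self, node: str) -> list[str]:
        """Bases b such that the k-mer node+b exists (node is a (k-1)-mer)."""
        return [b for b in BASES if self.has(node + b)]

    def in_bases(self, node: str) -> list[str]:
        return [b for b in BASES if self.has(b + node)]


def build_dbg(reads: Sequence[str], k: int) -> DeBruijnGraph:
    """Build the double-stranded de Bruijn graph of a read set at one k."""
    counts = count_kmers(reads, k)
    return DeBruijnGraph(counts, k)


def _unitigs(graph: DeBruijnGraph) -> list[tuple[str, list[str], bool, bool]]:
    """Extract maximal unbranched paths.

    Returns (sequence, canonical k-mers on the path, left_dead_end,
    right_dead_end) per unitig.  Each undirected unitig is emitted once, in
    deterministic orientation, seeded from canonical k-mers in sorted order.
    """
    k = graph.k
    visited: set[str] = set()
    out = []
    for seed in sorted(graph.counts):
        if seed in visited:
            continue
        path = [seed]
        path_set = {seed}
        # extend right
        cur = seed
        while True:
            node = cur[1:]
            outs = graph.out_bases(node)
            if len(outs) != 1 or len(graph.in_bases(node)) != 1:
                break
            nxt = node + outs[0]
            canon = min(nxt, revcomp(nxt))
            if canon in path_set or canon in visited:
                break  # cycle or junction into an emitted unitig
            path.append(nxt)
            path_set.add(canon)
            cur = nxt
        # extend left
        cur = seed
        left = []
        while True:
            node = cur[: k - 1]
            ins = graph.in_bases(node)
            if len(ins) != 1 or len(graph.out_bases(node)) != 1:
                break
            prv = ins[0] + node
            canon = min(prv, revcomp(prv))
            if canon in path_set or canon in visited:
                break
            left.append(prv)
            path_set.add(canon)
            cur = prv
        path = list(reversed(left)) + path
        canon_path = [min(p, revcomp(p)) for p in path]
        visited.update(canon_path)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        left_dead = not graph.in_bases(path[0][: k - 1])
        right_dead = not graph.out_bases(path[-1][1:])
        # canonical orientation for determinism; votes may flip it later
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
            left_dead, right_dead = right_dead, left_dead
        out.append((seq, canon_path, left_dead, right_dead))
    return out


def assemble_k(
    reads: Sequence[str],
    k: int,
    cov_cutoff: float = 50.0,
    min_contig_len: int = 100,
    samples: Optional[Sequence[str]] = None,
    tip_clip: bool = True,
) -> list[Contig]:
    """Assemble one k: tip-clip, delete low-multiplicity edges, report unitigs.

    Order of simplification: unitigs of the full graph are computed, dead-end
    unitigs shorter than 2k with mean multiplicity < cov_cutoff/4 are removed,
    then every k-mer with multiplicity < cov_cutoff is deleted and unitigs are
    recompressed.  Reported contigs have length >= min_contig_len and mean
    k-mer coverage >= cov_cutoff, carry per-sample read support, and are
    oriented by majority vote of the reads that contain their k-mers.
    """
    counts = count_kmers(reads, k)
    if not counts:
        return []
    if tip_clip:
        graph = DeBruijnGraph(counts, k)
        for seq, canon_path, ldead, rdead in _unitigs(graph):
            if not (ldead or rdead):
                continue
            if len(seq) >= 2 * k:
                continue
            mean_cov = sum(counts[c] for c in canon_path) / len(canon_path)
            if mean_cov < cov_cutoff / 4.0:
                for c in canon_path:
                    counts.pop(c, None)
    counts = {km: c for km, c in counts.items() if c >= cov_cutoff}
    if not counts:
        return []
    graph = DeBruijnGraph(counts, k)
    contigs = []
    for seq, canon_path, _, _ in _unitigs(graph):
        if len(seq) < min_contig_len:
            continue
        mean_cov = sum(counts[c] for c in canon_path) / len(canon_path)
        if mean_cov < cov_cutoff:
            continue
        contigs.append(Contig(seq=seq, k=k, mean_kmer_cov=mean_cov))
    _orient_and_support(contigs, reads, samples, k)
    contigs.sort(key=lambda c: c.seq)
    return contigs


def _orient_and_support(
    contigs: list[Contig], reads: Sequence[str], samples: Optional[Sequence[str]], k: int
) -> None:
    """Flip each contig to the majority read orientation; tally read support.

    A read supports a contig when it shares at least one canonical k-mer with
    it; its oriented k-mers vote for the contig's forward or reverse sense.
    """
    if not contigs:
        return
    fwd_sets: list[set[str]] = [
        {ctg.seq[i : i + k] for i in range(len(ctg.seq) - k + 1)} for ctg in contigs
    ]
    # forward-oriented lookup alongside the canonical one lets each read
    # position resolve with a single dict probe; scanning with stride k//2
    # still catches every read sharing >= k consecutive bases with a contig
    fwd_to_contig: dict[str, int] = {}
    for idx, fwd in enumerate(fwd_sets):
        for km in fwd:
            fwd_to_contig[km] = idx
    stride = max(1, k // 2)
    votes = [0] * len(contigs)
    for ridx, read in enumerate(reads):
        n = len(read)
        if n < k:
            continue
        touched: set[int] = set()
        positions = list(range(0, n - k + 1, stride))
        if positions[-1] != n - k:
            positions.append(n - k)
        for i in positions:
            km = read[i : i + k]
            idx = fwd_to_contig.get(km)
            if idx is not None:
                touched.add(idx)
                votes[idx] += 1
                continue
            kmrc = revcomp(km)
            idx = fwd_to_contig.get(kmrc)
            if idx is not None:
                touched.add(idx)
                votes[idx] -= 1
        if samples is not None:
            for idx in touched:
                s = samples[ridx]
                contigs[idx].read_support[s] = contigs[idx].read_support.get(s, 0) + 1
    for idx, ctg in enumerate(contigs):
        if votes[idx] < 0:
            ctg.seq = revcomp(ctg.seq)


def assemble_multik(
    reads: Sequence[str],
    cfg: AssemblyConfig = AssemblyConfig(),
    samples: Optional[Sequence[str]] = None,
    cov_cutoff: Optional[float] = None,
) -> list[Contig]:
    """Union of single-k assemblies over cfg.k_values (duplicates retained).

    Near-identical contigs produced at different k are resolved downstream by
    the similarity graph, exactly because agreement across k is evidence the
    assembly is right.
    """
    cutoff = cfg.cov_cutoff if cov_cutoff is None else cov_cutoff
    out: list[Contig] = []
    for k in cfg.k_values:
        out.extend(
            assemble_k(reads, k, cov_cutoff=cutoff, min_contig_len=cfg.min_contig_len, samples=samples)
        )
    for i, ctg in enumerate(out):
        ctg.id = f"k{ctg.k}_{i}"
    return out


def rescue_assemble(
    reads: Sequence[str],
    cfg: AssemblyConfig = AssemblyConfig(),
    samples: Optional[Sequence[str]] = None,
) -> Optional[Contig]:
    """Re-assemble one region's orphans at the relaxed (20x) cutoff.

    Invoked for genomic regions where the strict 50x pass left more than one
    candidate — usually fragments of one longer insertion.  Returns the single
    longest contig (ties: higher coverage, then lexicographically smaller
    sequence), or None.
    """
    contigs = assemble_multik(reads, cfg, samples=samples, cov_cutoff=cfg.rescue_cov_cutoff)
    if not contigs:
        return None
    return max(contigs, key=lambda c: (len(c.seq), c.mean_kmer_cov, _neg_lex(c.seq)))


class _neg_lex(str):
    """Inverts lexicographic comparison so max() prefers the smaller string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
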
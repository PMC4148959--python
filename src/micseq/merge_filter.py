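"""Candidate collection and false-candidate filtering.

Per-k assemblies of the same insertion are reconciled through a sequence
similarity graph: contigs are nodes, pairs aligning with e-value below 1e-10
are edges, and each connected component contributes its longest member as one
candidate.  Singleton nodes — sequences assembled at only one k — are kept as
candidates too.

Candidates then pass an ordered filter chain, each step recorded in an
append-only audit trail:

1. known/low-complexity — alignable to the reference (identity >= 0.95 over
   >= 90% of the candidate) or mostly DUST-masked;
2. anchor cluster — at least half of the supporting anchor reads must fall in
   one 4 kb window (a real insertion concentrates its anchors at one locus);
3. local reference — the candidate must not align to the reference sequence
   under its own anchor cluster (padded 1 kb);
4. contaminant — optional screen against a supplied contaminant FASTA.

Regions where more than one candidate survives are re-assembled at the
relaxed 20x cutoff (rescue) since the fragments usually belong to a single
longer insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from . import assemble as _assemble
from .align import AlignmentResult, Scoring, SeedIndex, evalue, smith_waterman
from .assemble import AssemblyConfig, Contig
from .dnautil import dust_fraction, revcomp
from .oea import OeaRecord

__all__ = [
    "FilterConfig",
    "SimilarityEdge",
    "AnchorCluster",
    "CandidateMicSeq",
    "local_align",
    "build_similarity_graph",
    "pick_representatives",
    "attach_anchor_records",
    "filter_known_and_lowcomplexity",
    "anchor_cluster_filter",
    "local_reference_filter",
    "contaminant_filter",
    "run_filter_chain",
    "rescue_regions",
]


@dataclass(slots=True)
class FilterConfig:
    evalue_edge: float = 1e-10
    ref_identity: float = 0.95
    ref_cov_frac: float = 0.9
    dust_frac: float = 0.8
    cluster_window: int = 4000
    cluster_min_frac: float = 0.5
    local_ref_pad: int = 1000
    seed_len: int = 15


@dataclass(slots=True)
class SimilarityEdge:
    contig_a: str
    contig_b: str
    evalue: float
    identity: float
    aln_len: int


@dataclass(slots=True)
class AnchorCluster:
    chrom: str
    window_start: int
    window_end: int
    in_window_count: int
    total_count: int

    @property
    def fraction(self) -> float:
        return self.in_window_count / self.total_count if self.total_count else 0.0


@dataclass(slots=True)
class CandidateMicSeq:
    id: str
    seq: str
    member_contigs: list[Contig] = field(default_factory=list)
    anchor_records: list[OeaRecord] = field(default_factory=list)
    anchor_cluster: Optional[AnchorCluster] = None
    filter_trail: list[tuple[str, str, str]] = field(default_factory=list)

    def record(self, filter_name: str, passed: bool, detail: str = "") -> None:
        self.filter_trail.append((filter_name, "pass" if passed else "fail", detail))

    @property
    def passed_all(self) -> bool:
        return all(v == "pass" for _, v, _ in self.filter_trail)


def local_align(a: str, b: str, scoring: Scoring = Scoring()) -> AlignmentResult:
    """Smith-Waterman with a Karlin-Altschul e-value attached."""
    res = smith_waterman(a, b, scoring)
    res.evalue = evalue(res.score, len(a), len(b), scoring)
    return res


def build_similarity_graph(
    contigs: Sequence[Contig], cfg: FilterConfig = FilterConfig()
) -> tuple[list[list[int]], list[SimilarityEdge]]:
    """Connected components of the contig similarity graph.

    Nodes are contig indices; an edge joins two contigs whose local alignment
    has e-value < cfg.evalue_edge.  A shared exact 15-mer is required before
    running the quadratic alignment — an alignment clearing 1e-10 needs a
    score far above what a seedless pair can reach, so the prefilter cannot
    change the graph.  Components (including singletons) are returned sorted
    for determinism.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(contigs)))
    edges: list[SimilarityEdge] = []
    seed_sets = []
    for c in contigs:
        s = set()
        for strand_seq in (c.seq, revcomp(c.seq)):
            for i in range(len(strand_seq) - cfg.seed_len + 1):
                s.add(strand_seq[i : i + cfg.seed_len])
        seed_sets.append(s)
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            if not (seed_sets[i] & seed_sets[j]):
                continue
            res = local_align(contigs[i].seq, contigs[j].seq)
            if res.evalue < cfg.evalue_edge:
                g.add_edge(i, j)
                edges.append(
                    SimilarityEdge(contigs[i].id, contigs[j].id, res.evalue, res.identity, res.aln_len)
                )
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort()
    return comps, edges


def pick_representatives(
    components: Sequence[Sequence[int]],
    contigs: Sequence[Contig],
    id_prefix: str = "cand",
) -> list[CandidateMicSeq]:
    """One candidate per component: the longest member.

    Ties break to higher mean k-mer coverage, then to the lexicographically
    smaller sequence.
    """
    cands = []
    for n, comp in enumerate(components):
        members = [contigs[i] for i in comp]
        best = max(members, key=lambda c: (len(c.seq), c.mean_kmer_cov, _assemble._neg_lex(c.seq)))
        cands.append(
            CandidateMicSeq(id=f"{id_prefix}{n}", seq=best.seq, member_contigs=members)
        )
    return cands


def attach_anchor_records(
    cand: CandidateMicSeq,
    records: Sequence[OeaRecord],
    cfg: FilterConfig = FilterConfig(),
    min_identity: float = 0.95,
) -> None:
    """Attach the OEA records whose orphan read maps onto the candidate.

    The same exact-seed + ungapped-extension rule used for carrier calling, so
    anchor support is recomputable from the pooled records alone.
    """
    idx = SeedIndex(cand.seq, cfg.seed_len)
    cand.anchor_records = [
        r for r in records if idx.ungapped_hit(r.orphan_seq, min_identity) is not None
    ]


def filter_known_and_lowcomplexity(
    cand: CandidateMicSeq,
    reference: dict[str, str],
    cfg: FilterConfig = FilterConfig(),
    ref_index: Optional[dict[str, SeedIndex]] = None,
) -> bool:
    """Screen against the reference genome and a DUST-style complexity mask.

    Fails when the candidate aligns to the reference with identity >=
    cfg.ref_identity over >= cfg.ref_cov_frac of its length (it is a known
    sequence), or when more than cfg.dust_frac of it is low-complexity.
    """
    frac = dust_fraction(cand.seq)
    if frac > cfg.dust_frac:
        cand.record("known_lowcomplexity", False, f"dust_masked={frac:.2f}")
        return False
    hit = _best_reference_hit(cand.seq, reference, cfg, ref_index)
    if hit is not None:
        ident, cov, chrom = hit
        if ident >= cfg.ref_identity and cov >= cfg.ref_cov_frac:
            cand.record("known_lowcomplexity", False, f"ref_hit={chrom}:id{ident:.2f}:cov{cov:.2f}")
            return False
    cand.record("known_lowcomplexity", True)
    return True


def _best_reference_hit(
    seq: str,
    reference: dict[str, str],
    cfg: FilterConfig,
    ref_index: Optional[dict[str, SeedIndex]],
) -> Optional[tuple[float, float, str]]:
    """Best (identity, candidate-coverage, chrom) over seed-supported loci."""
    best = None
    for chrom, ref_seq in reference.items():
        idx = ref_index[chrom] if ref_index else SeedIndex(ref_seq, cfg.seed_len)
        for strand_seq in (seq, revcomp(seq)):
            loci = _seed_loci(idx, strand_seq)
            for pos in loci:
                lo = max(0, pos - len(seq) - 100)
                hi = min(len(ref_seq), pos + 2 * len(seq) + 100)
                res = smith_waterman(strand_seq, ref_seq[lo:hi])
                cov = (res.a_end - res.a_start) / len(seq)
                cur = (res.identity, cov, chrom)
                if best is None or (cur[0] * cur[1]) > (best[0] * best[1]):
                    best = cur
    return best


def _seed_loci(idx: SeedIndex, query: str, max_loci: int = 4, min_gap: int = 500) -> list[int]:
    """Distinct subject loci supported by exact seeds, deduplicated by distance."""
    positions = sorted(j for _, j in idx.seed_positions(query))
    loci: list[int] = []
    for p in positions:
        if not loci or p - loci[-1] > min_gap:
            loci.append(p)
        if len(loci) >= max_loci:
            break
    return loci


def find_anchor_cluster(
    records: Sequence[OeaRecord], window: int = 4000
) -> Optional[AnchorCluster]:
    """Leftmost maximal-count ``window``-nt window over anchor positions.

    Anchors on several chromosomes are evaluated on the modal chromosome while
    still counting toward the total (diluting the fraction).  Duplicate pair
    ids count once.
    """
    seen: dict[str, OeaRecord] = {}
    for r in records:
        seen.setdefault(r.pair_id, r)
    recs = list(seen.values())
    if not recs:
        return None
    by_chrom: dict[str, list[int]] = {}
    for r in recs:
        by_chrom.setdefault(r.anchor_chrom, []).append(r.anchor_pos)
    modal = max(sorted(by_chrom), key=lambda c: len(by_chrom[c]))
    pos = sorted(by_chrom[modal])
    total = len(recs)
    best_count, best_start = 0, pos[0]
    j = 0
    for i in range(len(pos)):
        while pos[j] < pos[i] - window + 1:
            j += 1
        count = i - j + 1
        start = pos[j]
        if count > best_count or (count == best_count and start < best_start):
            best_count, best_start = count, start
    return AnchorCluster(
        chrom=modal,
        window_start=best_start,
        window_end=best_start + window,
        in_window_count=best_count,
        total_count=total,
    )


def anchor_cluster_filter(
    cand: CandidateMicSeq, cfg: FilterConfig = FilterConfig()
) -> bool:
    """Pass iff >= cfg.cluster_min_frac of anchors share one 4 kb window."""
    cluster = find_anchor_cluster(cand.anchor_records, cfg.cluster_window)
    cand.anchor_cluster = cluster
    if cluster is None:
        cand.record("anchor_cluster", False, "no_anchor_records")
        return False
    ok = cluster.fraction >= cfg.cluster_min_frac
    cand.record(
        "anchor_cluster", ok,
        f"{cluster.in_window_count}/{cluster.total_count}@{cluster.chrom}:{cluster.window_start}",
    )
    return ok


def local_reference_filter(
    cand: CandidateMicSeq, reference: dict[str, str], cfg: FilterConfig = FilterConfig()
) -> bool:
    """Fail candidates alignable to the reference under their own anchors.

    The reference window is the anchor cluster padded by cfg.local_ref_pad on
    each side, clipped at chromosome edges.
    """
    cluster = cand.anchor_cluster
    if cluster is None:
        raise ValueError(f"{cand.id}: anchor_cluster_filter must run first")
    ref_seq = reference.get(cluster.chrom, "")
    lo = max(0, cluster.window_start - cfg.local_ref_pad)
    hi = min(len(ref_seq), cluster.window_end + cfg.local_ref_pad)
    segment = ref_seq[lo:hi]
    if segment:
        for strand_seq in (cand.seq, revcomp(cand.seq)):
            res = smith_waterman(strand_seq, segment)
            cov = (res.a_end - res.a_start) / len(cand.seq)
            if res.identity >= cfg.ref_identity and cov >= cfg.ref_cov_frac:
                cand.record("local_reference", False, f"id{res.identity:.2f}:cov{cov:.2f}")
                return False
    cand.record("local_reference", True)
    return True


def contaminant_filter(
    cand: CandidateMicSeq,
    contaminants: Optional[Sequence[tuple[str, str]]],
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """Fail candidates alignable to any supplied contaminant sequence."""
    if not contaminants:
        cand.record("contaminant", True, "skipped")
        return True
    for name, cont in contaminants:
        idx = SeedIndex(cont, cfg.seed_len)
        for strand_seq in (cand.seq, revcomp(cand.seq)):
            if not _seed_loci(idx, strand_seq):
                continue
            res = smith_waterman(strand_seq, cont)
            cov = (res.a_end - res.a_start) / len(cand.seq)
            if res.identity >= cfg.ref_identity and cov >= cfg.ref_cov_frac:
                cand.record("contaminant", False, f"{name}:id{res.identity:.2f}:cov{cov:.2f}")
                return False
    cand.record("contaminant", True)
    return True


def run_filter_chain(
    cands: Sequence[CandidateMicSeq],
    reference: dict[str, str],
    records: Sequence[OeaRecord],
    cfg: FilterConfig = FilterConfig(),
    contaminants: Optional[Sequence[tuple[str, str]]] = None,
    ref_index: Optional[dict[str, SeedIndex]] = None,
) -> list[CandidateMicSeq]:
    """Apply the fixed filter order; returns the candidates that pass all.

    Every candidate's trail records each applied filter exactly once; a
    failing candidate is not subjected to later filters (its trail ends at
    the failure).
    """
    survivors = []
    for cand in cands:
        if not cand.anchor_records:
            attach_anchor_records(cand, records, cfg)
        if not filter_known_and_lowcomplexity(cand, reference, cfg, ref_index):
            continue
        if not anchor_cluster_filter(cand, cfg):
            continue
        if not local_reference_filter(cand, reference, cfg):
            continue
        if not contaminant_filter(cand, contaminants, cfg):
            continue
        survivors.append(cand)
    return survivors


def rescue_regions(
    survivors: list[CandidateMicSeq],
    records: Sequence[OeaRecord],
    asm_cfg: AssemblyConfig,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[CandidateMicSeq], int]:
    """Re-assemble regions holding more than one surviving candidate at 20x.

    Two candidates share a region when their anchor-cluster windows overlap on
    one chromosome.  Each multi-candidate region is re-assembled from the
    orphan reads anchored inside the merged span using the relaxed cutoff; the
    longest rescued contig replaces the region's candidates (it must be at
    least as long as the longest of them).  Returns (updated candidates,
    number of rescued regions).
    """
    from .oea import orient_orphan

    groups: list[list[CandidateMicSeq]] = []
    for cand in sorted(survivors, key=lambda c: (c.anchor_cluster.chrom, c.anchor_cluster.window_start)):
        placed = False
        for grp in groups:
            last = grp[-1].anchor_cluster
            cur = cand.anchor_cluster
            if cur.chrom == last.chrom and cur.window_start < last.window_end:
                grp.append(cand)
                placed = True
                break
        if not placed:
            groups.append([cand])
    out: list[CandidateMicSeq] = []
    n_rescued = 0
    for grp in groups:
        if len(grp) == 1:
            out.append(grp[0])
            continue
        chrom = grp[0].anchor_cluster.chrom
        lo = min(c.anchor_cluster.window_start for c in grp)
        hi = max(c.anchor_cluster.window_end for c in grp)
        region_recs = [
            r for r in records
            if r.anchor_chrom == chrom and lo <= r.anchor_pos < hi
        ]
        reads = [orient_orphan(r) for r in region_recs]
        samp = [r.sample_id for r in region_recs]
        contig = _assemble.rescue_assemble(reads, asm_cfg, samples=samp)
        longest = max(grp, key=lambda c: len(c.seq))
        if contig is None or len(contig.seq) < len(longest.seq):
            out.extend(grp)
            continue
        n_rescued += 1
        rescued = CandidateMicSeq(
            id=longest.id + "_rescued",
            seq=contig.seq,
            member_contigs=[contig],
        )
        rescued.record("rescue", True, f"{chrom}:{lo}-{hi} replaced {len(grp)} candidates")
        attach_anchor_records(rescued, records, cfg)
        cluster = find_anchor_cluster(rescued.anchor_records, cfg.cluster_window)
        rescued.anchor_cluster = cluster
        out.append(rescued)
    return out, n_rescued
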
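"""End-to-end orchestration: trim -> OEA pooling -> assembly -> filters -> calls.

`discover_micseqs` is the in-memory engine: it consumes per-sample streams of
(ReadPair, mate1 alignment, mate2 alignment) and returns final micSeq calls
plus a MANIFEST of stage counts.  `run_pipeline` is the file-based wrapper
used by the command line: it stages FASTQ/SAM inputs, runs the engine and
writes the report files.

Assembly modes mirror the two pooling strategies: ``joint`` pools orphans
from all populations (maximal depth for shared insertions),
``per_population`` assembles each population separately (sensitive to
population-private insertions), and ``both`` unions the two, deduplicating
calls whose sequences align at >= 95% identity over >= 90% of the shorter
and keeping the longer.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align import smith_waterman
from .annotate import CarrierConfig, MicSeqCall, call_carriers, classify_gene_context, estimate_breakpoint
from .assemble import AssemblyConfig, assemble_multik
from .formats import BedFeature, read_alignments, read_bed, read_fasta, read_fastq_pairs, write_fasta
from .merge_filter import (
    CandidateMicSeq,
    FilterConfig,
    build_similarity_graph,
    pick_representatives,
    rescue_regions,
    run_filter_chain,
)
from .oea import OeaRecord, PoolResult, orient_orphan, pool_oea
from .preprocess import TrimConfig, TrimStats, trim_pair

__all__ = ["PipelineConfig", "PipelineResult", "discover_micseqs", "run_pipeline"]


@dataclass(slots=True)
class PipelineConfig:
    trim: TrimConfig = field(default_factory=TrimConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    carrier: CarrierConfig = field(default_factory=CarrierConfig)
    min_mapq: int = 20
    insert_range: Optional[tuple[float, float]] = None
    mode: str = "joint"  # joint | per_population | both

    def __post_init__(self):
        if self.mode not in ("joint", "per_population", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(slots=True)
class PipelineResult:
    calls: list[MicSeqCall]
    candidates: list[CandidateMicSeq]  # every candidate with its filter trail
    pool: PoolResult
    manifest: dict


def discover_micseqs(
    sample_streams: Iterable[Iterable[tuple]],
    reference: dict[str, str],
    cfg: PipelineConfig = PipelineConfig(),
    contaminants: Optional[Sequence[tuple[str, str]]] = None,
    annotation: Optional[Sequence[BedFeature]] = None,
) -> PipelineResult:
    """Run the full discovery pipeline over in-memory per-sample streams."""
    trim_stats = TrimStats()

    def _trimmed(stream):
        for pair, a1, a2 in stream:
            trim_stats.pairs_in += 1
            trimmed = trim_pair(pair, cfg.trim)
            if trimmed is None:
                trim_stats.pairs_dropped += 1
                continue
            trim_stats.pairs_kept += 1
            yield trimmed, a1, a2

    pool = pool_oea(
        (_trimmed(s) for s in sample_streams),
        min_mapq=cfg.min_mapq,
        insert_range=cfg.insert_range,
        known_chroms=set(reference),
    )
    all_candidates: list[CandidateMicSeq] = []
    survivors: list[CandidateMicSeq] = []
    n_contigs = 0
    n_rescued = 0
    groupings: list[tuple[str, str, list[OeaRecord]]] = []
    for chrom in sorted(pool.by_chrom):
        recs = pool.by_chrom[chrom]
        if cfg.mode in ("joint", "both"):
            groupings.append((chrom, f"{chrom}.joint", recs))
        if cfg.mode in ("per_population", "both"):
            pops = sorted({r.population for r in recs})
            for p in pops:
                groupings.append((chrom, f"{chrom}.{p}", [r for r in recs if r.population == p]))
    for chrom, label, recs in groupings:
        reads = [orient_orphan(r) for r in recs]
        samples = [r.sample_id for r in recs]
        contigs = assemble_multik(reads, cfg.assembly, samples=samples)
        n_contigs += len(contigs)
        if not contigs:
            continue
        comps, _ = build_similarity_graph(contigs, cfg.filters)
        cands = pick_representatives(comps, contigs, id_prefix=f"{label}.cand")
        chrom_recs = pool.by_chrom[chrom]
        passed = run_filter_chain(
            cands, reference, chrom_recs, cfg.filters, contaminants=contaminants
        )
        passed, k = rescue_regions(passed, chrom_recs, cfg.assembly, cfg.filters)
        n_rescued += k
        # rescued candidates re-enter the filter chain (their trail keeps both passes)
        final = []
        for c in passed:
            if c.filter_trail and c.filter_trail[0][0] == "rescue":
                if run_filter_chain([c], reference, chrom_recs, cfg.filters, contaminants=contaminants):
                    final.append(c)
            else:
                final.append(c)
        all_candidates.extend(cands)
        survivors.extend(final)
    if cfg.mode == "both":
        survivors = _dedupe_calls(survivors)
    # per-sample orphan reads for post-hoc carrier recomputation; every sample
    # seen in the input participates, orphan-less samples as non-carriers
    per_sample: dict[str, tuple[str, list[str]]] = {
        sid: (popn, []) for sid, popn in pool.samples.items()
    }
    for recs in pool.by_chrom.values():
        for r in recs:
            per_sample.setdefault(r.sample_id, (r.population, []))[1].append(r.orphan_seq)
    calls: list[MicSeqCall] = []
    for cand in survivors:
        breakpoint = estimate_breakpoint(cand, cfg.carrier.breakpoint_tolerance)
        carriers, pop_freq, overall = call_carriers(cand.seq, per_sample, cfg.carrier)
        if overall < cfg.carrier.min_pop_freq:
            cand.record("min_pop_freq", False, f"carrier_frac={overall:.4f}")
            continue
        gene_context = (
            classify_gene_context(breakpoint, annotation) if annotation is not None else "intergenic"
        )
        calls.append(
            MicSeqCall(
                id=cand.id,
                seq=cand.seq,
                breakpoint=breakpoint,
                carriers=carriers,
                pop_freq=pop_freq,
                gene_context=gene_context,
                candidate=cand,
            )
        )
    calls.sort(key=lambda c: (c.breakpoint.chrom, c.breakpoint.start, c.id))
    for i, call in enumerate(calls):
        call.id = f"micseq{i + 1}"
    manifest = _manifest(trim_stats, pool, n_contigs, all_candidates, survivors, n_rescued, calls)
    return PipelineResult(calls=calls, candidates=all_candidates, pool=pool, manifest=manifest)


def _dedupe_calls(cands: list[CandidateMicSeq]) -> list[CandidateMicSeq]:
    """Union semantics for mode=both: near-identical sequences collapse.

    Two candidates are duplicates when they align at >= 95% identity over
    >= 90% of the shorter; the longer survives.
    """
    kept: list[CandidateMicSeq] = []
    for cand in sorted(cands, key=lambda c: (-len(c.seq), c.seq)):
        dup = False
        for other in kept:
            res = smith_waterman(cand.seq, other.seq)
            short = min(len(cand.seq), len(other.seq))
            cov = (res.a_end - res.a_start) / short if short else 0.0
            if res.identity >= 0.95 and cov >= 0.9:
                dup = True
                break
        if not dup:
            kept.append(cand)
    return kept


def _manifest(trim_stats, pool, n_contigs, candidates, survivors, n_rescued, calls) -> dict:
    filter_counts: dict[str, dict[str, int]] = {}
    for cand in candidates:
        for name, verdict, _ in cand.filter_trail:
            d = filter_counts.setdefault(name, {"pass": 0, "fail": 0})
            d[verdict] += 1
    return {
        "pairs_in": trim_stats.pairs_in,
        "pairs_after_trim": trim_stats.pairs_kept,
        "pairs_dropped_by_trim": trim_stats.pairs_dropped,
        "pairs_classified": pool.pairs_in,
        "class_counts": {c.value: n for c, n in pool.class_counts.items()},
        "oea_records": sum(len(v) for v in pool.by_chrom.values()),
        "contigs": n_contigs,
        "candidates": len(candidates),
        "candidates_after_filters": len(survivors),
        "regions_rescued": n_rescued,
        "filter_counts": filter_counts,
        "calls": len(calls),
    }


def run_pipeline(
    reference_fasta,
    samples: Sequence[dict],
    outdir,
    cfg: PipelineConfig = PipelineConfig(),
    contaminants_fasta=None,
    annotation_bed=None,
) -> PipelineResult:
    """File-based pipeline: read inputs, run discovery, write reports.

    ``samples`` rows need keys id, population, fastq1, fastq2, alignments.
    Writes micseqs.fasta, calls.tsv, filter_report.tsv, oea.tsv, clusters.bed
    and MANIFEST.json into ``outdir``.
    """
    os.makedirs(outdir, exist_ok=True)
    reference = dict(read_fasta(reference_fasta))
    contaminants = read_fasta(contaminants_fasta) if contaminants_fasta else None
    annotation = read_bed(annotation_bed) if annotation_bed else None

    def sample_stream(row):
        alns = {
            pid: (a1, a2) for pid, a1, a2 in read_alignments(row["alignments"])
        }
        for pair in read_fastq_pairs(row["fastq1"], row["fastq2"], row["id"], row["population"]):
            if pair.pair_id not in alns:
                raise ValueError(f"{row['id']}: no alignment for pair {pair.pair_id!r}")
            a1, a2 = alns[pair.pair_id]
            yield pair, a1, a2

    result = discover_micseqs(
        (sample_stream(row) for row in samples),
        reference,
        cfg,
        contaminants=contaminants,
        annotation=annotation,
    )
    _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir) -> None:
    write_fasta(
        [(c.id, c.seq) for c in result.calls], os.path.join(outdir, "micseqs.fasta")
    )
    pops = sorted({p for c in result.calls for p in c.pop_freq})
    with open(os.path.join(outdir, "calls.tsv"), "w") as fh:
        fh.write(
            "micseq_id\tchrom\tbp_start\tbp_end\tlength\tgene_context\t"
            + "\t".join(f"freq_{p}" for p in pops) + "\n"
        )
        for c in result.calls:
            freqs = "\t".join(f"{c.pop_freq.get(p, 0.0):.4f}" for p in pops)
            fh.write(
                f"{c.id}\t{c.breakpoint.chrom}\t{c.breakpoint.start}\t{c.breakpoint.end}\t"
                f"{len(c.seq)}\t{c.gene_context}\t{freqs}\n"
            )
    with open(os.path.join(outdir, "filter_report.tsv"), "w") as fh:
        fh.write("candidate_id\tfilter\tverdict\tdetail\n")
        for cand in result.candidates:
            for name, verdict, detail in cand.filter_trail:
                fh.write(f"{cand.id}\t{name}\t{verdict}\t{detail}\n")
    with open(os.path.join(outdir, "oea.tsv"), "w") as fh:
        fh.write("pair_id\tsample\tpopulation\tanchor_chrom\tanchor_pos\tanchor_strand\n")
        for chrom in sorted(result.pool.by_chrom):
            for r in result.pool.by_chrom[chrom]:
                fh.write(
                    f"{r.pair_id}\t{r.sample_id}\t{r.population}\t"
                    f"{r.anchor_chrom}\t{r.anchor_pos}\t{r.anchor_strand}\n"
                )
    with open(os.path.join(outdir, "clusters.bed"), "w") as fh:
        for call in result.calls:
            cl = call.candidate.anchor_cluster if call.candidate else None
            if cl:
                fh.write(f"{cl.chrom}\t{cl.window_start}\t{cl.window_end}\t{call.id}\n")
    with open(os.path.join(outdir, "MANIFEST.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1)
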
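"""Breakpoint estimation, read mapping, carrier calling and gene context."""

import random

import numpy as np
import pytest

from micseq.annotate import (
    CarrierConfig,
    call_carriers,
    classify_gene_context,
    estimate_breakpoint,
    map_reads_to_micseq,
    score_evidence,
)
from micseq.dnautil import revcomp
from micseq.formats import BedFeature, GenomicInterval
from micseq.merge_filter import CandidateMicSeq, find_anchor_cluster
from micseq.oea import OeaRecord
from tests.conftest import coverage_oracle, random_dna

CFG = CarrierConfig()


def _rec(pos, strand, chrom="chr1", read_len=50, pid=None):
    return OeaRecord(
        orphan_seq="A" * read_len, orphan_qual=np.full(read_len, 30),
        anchor_chrom=chrom, anchor_pos=pos, anchor_end=pos + read_len,
        anchor_strand=strand, sample_id="s", population="AFR",
        pair_id=pid or f"{pos}{strand}",
    )


def _candidate(records):
    cand = CandidateMicSeq("c", "A" * 200, anchor_records=records)
    cand.anchor_cluster = find_anchor_cluster(records, 4000)
    return cand


def test_breakpoint_midpoint_of_agreeing_flanks():
    recs = [_rec(950, "+"), _rec(1010, "-")]  # + anchor ends at 1000
    bp = estimate_breakpoint(_candidate(recs))
    assert (bp.chrom, bp.start, bp.end) == ("chr1", 1005, 1005)


def test_breakpoint_interval_fallback_for_one_sided_evidence():
    recs = [_rec(1000 + i * 200, "+") for i in range(5)]
    bp = estimate_breakpoint(_candidate(recs))
    assert bp.start == 1000 and bp.end == 1850
    cluster = _candidate(recs).anchor_cluster
    assert cluster.window_start <= bp.start and bp.end <= cluster.window_end


def test_breakpoint_for_a_micseq30_like_cluster():
    """Anchors spanning chrX:131,393,154-131,393,947 place the call inside the span."""
    rng = random.Random(1)
    span_lo, span_hi = 131_393_154, 131_393_947
    recs = []
    for i in range(20):
        pos = rng.randrange(span_lo, 131_393_592 - 90)
        recs.append(_rec(pos, "+", chrom="chrX", read_len=90, pid=f"p{i}"))
    for i in range(20):
        pos = rng.randrange(131_393_592, span_hi - 90)
        recs.append(_rec(pos, "-", chrom="chrX", read_len=90, pid=f"m{i}"))
    bp = estimate_breakpoint(_candidate(recs))
    assert bp.chrom == "chrX"
    assert span_lo <= bp.start <= bp.end <= span_hi


def test_breakpoint_requires_anchor_cluster():
    cand = CandidateMicSeq("c", "A" * 200)
    with pytest.raises(ValueError):
        estimate_breakpoint(cand)


def test_breakpoint_stays_inside_cluster_window_on_random_inputs():
    rng = random.Random(2)
    for _ in range(30):
        recs = [
            _rec(50_000 + rng.randrange(0, 3000), rng.choice("+-"), pid=f"p{i}")
            for i in range(rng.randrange(2, 30))
        ]
        cand = _candidate(recs)
        bp = estimate_breakpoint(cand)
        cl = cand.anchor_cluster
        lo = min(r.anchor_pos for r in recs)
        hi = max(r.anchor_end for r in recs)
        assert lo <= bp.start <= bp.end <= hi


# ----------------------------------------------------------- read mapping


def test_copied_read_hits_with_full_span_coverage():
    rng = random.Random(3)
    mic = random_dna(rng, 300)
    hits, cov = map_reads_to_micseq([mic[100:200]], mic, CFG)
    assert hits == [True]
    assert cov[100:200].min() == 1 and cov.sum() == 100
    hits_rc, _ = map_reads_to_micseq([revcomp(mic[100:200])], mic, CFG)
    assert hits_rc == [True]


def test_random_reads_never_hit():
    rng = random.Random(4)
    mic = random_dna(rng, 300)
    reads = [random_dna(rng, 100) for _ in range(1000)]
    hits, cov = map_reads_to_micseq(reads, mic, CFG)
    assert sum(hits) == 0 and cov.sum() == 0


def test_coverage_matches_interval_stabbing_oracle():
    rng = random.Random(5)
    mic = random_dna(rng, 300)
    spans = []
    reads = []
    for _ in range(150):
        s = rng.randrange(0, 250)
        e = min(300, s + rng.randrange(30, 100))
        spans.append((s, e))
        reads.append(mic[s:e])
    _, cov = map_reads_to_micseq(reads, mic, CFG)
    assert np.array_equal(cov, coverage_oracle(spans, 300))


def test_mismatched_read_respects_identity_threshold():
    rng = random.Random(6)
    mic = random_dna(rng, 300)
    read = list(mic[50:150])
    for i in range(20, 30):  # 10% mismatches -> below 0.95
        read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
    hits, _ = map_reads_to_micseq(["".join(read)], mic, CFG)
    assert hits == [False]


# -------------------------------------------------------- carrier calling


def _orphans(mic, n_hit, n_noise, rng):
    reads = [mic[rng.randrange(0, len(mic) - 60) :][:60] for _ in range(n_hit)]
    reads += [random_dna(rng, 60) for _ in range(n_noise)]
    return reads


def test_carrier_threshold_at_three_reads():
    rng = random.Random(7)
    mic = random_dna(rng, 300)
    samples = {
        "carrier": ("AFR", _orphans(mic, 3, 2, rng)),
        "noncarrier": ("AFR", _orphans(mic, 2, 3, rng)),
        "empty": ("EUR", _orphans(mic, 0, 4, rng)),
    }
    counts, pop_freq, overall = call_carriers(mic, samples, CFG)
    assert counts["carrier"] == 3 and counts["noncarrier"] == 2
    assert pop_freq == {"AFR": 0.5, "EUR": 0.0}
    assert overall == pytest.approx(1 / 3)


def test_raising_carrier_threshold_is_monotone():
    rng = random.Random(8)
    mic = random_dna(rng, 300)
    samples = {
        f"s{i}": ("AFR", _orphans(mic, rng.randrange(0, 6), 2, rng)) for i in range(12)
    }
    prev = 1.0
    for thresh in (1, 2, 3, 4, 5):
        cfg = CarrierConfig(min_reads_carrier=thresh)
        _, pop_freq, _ = call_carriers(mic, samples, cfg)
        assert pop_freq["AFR"] <= prev
        prev = pop_freq["AFR"]


def test_pop_freq_invariant_to_sample_order():
    rng = random.Random(9)
    mic = random_dna(rng, 300)
    samples = {f"s{i}": ("AFR" if i % 2 else "EUR", _orphans(mic, i % 5, 1, rng)) for i in range(10)}
    ref = call_carriers(mic, samples, CFG)
    reordered = dict(reversed(list(samples.items())))
    assert call_carriers(mic, reordered, CFG) == ref


# ----------------------------------------------------------- gene context


ANNOTATION = [
    BedFeature(GenomicInterval("chr8", 101_700_000, 101_720_000), "PABPC1", "gene"),
    BedFeature(GenomicInterval("chr8", 101_715_280, 101_715_513), "PABPC1_3utr", "utr"),
    BedFeature(GenomicInterval("chr8", 101_710_000, 101_715_280), "PABPC1_intron", "intron"),
    BedFeature(GenomicInterval("chr8", 101_705_000, 101_710_000), "PABPC1_exon", "exon"),
]


def test_breakpoint_in_utr():
    bp = GenomicInterval("chr8", 101_715_400, 101_715_400)
    assert classify_gene_context(bp, ANNOTATION) == "utr"


def test_exon_takes_precedence_over_gene_body():
    bp = GenomicInterval("chr8", 101_706_000, 101_706_000)
    assert classify_gene_context(bp, ANNOTATION) == "exon"


def test_flank_within_5kb_of_gene():
    bp = GenomicInterval("chr8", 101_697_000, 101_697_000)  # 3 kb upstream
    assert classify_gene_context(bp, ANNOTATION) == "flank_5kb"


def test_far_breakpoint_is_intergenic():
    bp = GenomicInterval("chr8", 101_900_000, 101_900_000)
    assert classify_gene_context(bp, ANNOTATION) == "intergenic"


# -------------------------------------------------------------- evidence


def test_evidence_flagging_and_control_means():
    """Treatment 72 vs control 7 reads, verified against direct counting."""
    rng = random.Random(10)
    mic = random_dna(rng, 300)
    treatment = {
        f"tf{j}": [mic[rng.randrange(0, 240) :][:60] for _ in range(72)] for j in range(4)
    }
    control = {
        f"ctl{j}": [mic[rng.randrange(0, 240) :][:60] for _ in range(7)]
        + [random_dna(rng, 60) for _ in range(65)]
        for j in range(4)
    }
    out = score_evidence({"m1": mic}, treatment, control, expressed_threshold=100)
    entry = out["m1"]
    assert entry["counts"] == {f"tf{j}": 72 for j in range(4)}
    assert entry["control_counts"] == {f"ctl{j}": 7 for j in range(4)}
    assert entry["treatment_mean"] == pytest.approx(72.0)
    assert entry["control_mean"] == pytest.approx(7.0)
    assert not entry["flagged"]  # 72 <= 100
    expressed = {"rna1": [mic[rng.randrange(0, 240) :][:60] for _ in range(150)]}
    out2 = score_evidence({"m1": mic}, expressed, expressed_threshold=100)
    assert out2["m1"]["flagged"] and out2["m1"]["counts"]["rna1"] == 150
    silent = score_evidence({"m1": mic}, {"rna1": [random_dna(rng, 60) for _ in range(50)]})
    assert not silent["m1"]["flagged"] and silent["m1"]["counts"]["rna1"] == 0
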
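"""Similarity graph, representative picking and the false-candidate filters."""

import random

import numpy as np
import pytest

from micseq.assemble import Contig
from micseq.merge_filter import (
    CandidateMicSeq,
    FilterConfig,
    anchor_cluster_filter,
    attach_anchor_records,
    build_similarity_graph,
    contaminant_filter,
    filter_known_and_lowcomplexity,
    find_anchor_cluster,
    local_align,
    local_reference_filter,
    pick_representatives,
    run_filter_chain,
)
from micseq.oea import OeaRecord
from tests.conftest import anchor_window_oracle, random_dna, sw_score_oracle

CFG = FilterConfig()


def _contig(seq, k=19, cov=60.0, cid="c"):
    return Contig(seq=seq, k=k, mean_kmer_cov=cov, id=cid)


def _rec(pos, strand="+", chrom="chr1", pid=None, seq=None, rng=None):
    seq = seq or random_dna(rng or random.Random(pos), 50)
    return OeaRecord(
        orphan_seq=seq, orphan_qual=np.full(len(seq), 30),
        anchor_chrom=chrom, anchor_pos=pos, anchor_end=pos + 50, anchor_strand=strand,
        sample_id="s1", population="AFR", pair_id=pid or f"p{pos}.{strand}",
    )


# ------------------------------------------------------------- local_align


def test_identical_sequences_align_perfectly(jit_warm):
    rng = random.Random(1)
    seq = random_dna(rng, 300)
    res = local_align(seq, seq)
    assert res.identity == 1.0
    assert res.aln_len == 300
    assert res.evalue < 1e-50


def test_random_pairs_never_clear_the_edge_threshold(jit_warm):
    rng = random.Random(2)
    for _ in range(100):
        res = local_align(random_dna(rng, 300), random_dna(rng, 300))
        assert res.evalue > 1e-10


def test_score_matches_quadratic_dp_oracle(jit_warm):
    rng = random.Random(3)
    for _ in range(50):
        a = random_dna(rng, rng.randrange(10, 80))
        b = random_dna(rng, rng.randrange(10, 80))
        if rng.random() < 0.5:  # make some pairs genuinely related
            b = a[: rng.randrange(5, len(a))] + b
        assert local_align(a, b).score == sw_score_oracle(a, b)


# --------------------------------------------------- similarity graph


def test_similar_contigs_group_and_unrelated_stay_apart(jit_warm):
    rng = random.Random(4)
    base = random_dna(rng, 300)
    a, b = _contig(base, 19, cid="A"), _contig(base, 23, cid="B")
    c = _contig(random_dna(rng, 300), 19, cid="C")
    comps, edges = build_similarity_graph([a, b, c], CFG)
    assert comps == [[0, 1], [2]]
    assert len(edges) == 1 and {edges[0].contig_a, edges[0].contig_b} == {"A", "B"}


def test_chain_components_close_transitively(jit_warm):
    rng = random.Random(5)
    core = random_dna(rng, 400)
    a = _contig(core[:250], cid="A")
    b = _contig(core[50:350], cid="B")
    c = _contig(core[150:400], cid="C")  # A vs C share only 100 nt
    comps, _ = build_similarity_graph([a, b, c], CFG)
    assert comps == [[0, 1, 2]]


def test_single_k_contig_survives_as_singleton(jit_warm):
    rng = random.Random(6)
    lone = _contig(random_dna(rng, 150), 31, cid="L")
    comps, _ = build_similarity_graph([lone], CFG)
    cands = pick_representatives(comps, [lone])
    assert len(cands) == 1 and cands[0].seq == lone.seq


def test_representative_tie_breaking():
    rng = random.Random(7)
    s220a, s220b = sorted([random_dna(rng, 220), random_dna(rng, 220)])
    members = [
        _contig(random_dna(rng, 180), cov=90, cid="short"),
        _contig(s220b, cov=70, cid="hi"),
        _contig(s220a, cov=55, cid="lo"),
        _contig(s220a, cov=70, cid="hi_lex_small"),
    ]
    (cand,) = pick_representatives([[0, 1, 2, 3]], members)
    assert len(cand.seq) == 220
    assert cand.seq == s220a  # among cov-70 ties the smaller sequence wins


def test_representative_length_is_component_max():
    rng = random.Random(8)
    for _ in range(20):
        members = [_contig(random_dna(rng, rng.randrange(100, 400))) for _ in range(rng.randrange(1, 6))]
        (cand,) = pick_representatives([list(range(len(members)))], members)
        assert len(cand.seq) == max(len(m.seq) for m in members)


# ------------------------------------------------------------- filters


@pytest.fixture(scope="module")
def reference():
    rng = random.Random(9)
    return {"chr1": random_dna(rng, 60_000)}


def test_reference_copy_fails_known_screen(reference, jit_warm):
    cand = CandidateMicSeq("c1", reference["chr1"][10_000:10_300])
    assert not filter_known_and_lowcomplexity(cand, reference, CFG)
    assert cand.filter_trail[0][:2] == ("known_lowcomplexity", "fail")


def test_dinucleotide_repeat_fails_complexity_screen(reference):
    cand = CandidateMicSeq("c2", "AT" * 100)
    assert not filter_known_and_lowcomplexity(cand, reference, CFG)
    assert "dust" in cand.filter_trail[0][2]


def test_novel_sequence_passes_both_screens(reference, jit_warm):
    cand = CandidateMicSeq("c3", random_dna(random.Random(10), 300))
    assert filter_known_and_lowcomplexity(cand, reference, CFG)


def test_tight_anchor_cluster_passes():
    recs = [_rec(1000 + i * 50) for i in range(10)]
    cand = CandidateMicSeq("c", "A" * 100, anchor_records=recs)
    assert anchor_cluster_filter(cand, CFG)
    assert cand.anchor_cluster.fraction == 1.0


def test_dispersed_anchors_fail():
    recs = [_rec(i * 10_000) for i in range(10)]
    cand = CandidateMicSeq("c", "A" * 100, anchor_records=recs)
    assert not anchor_cluster_filter(cand, CFG)
    assert cand.anchor_cluster.in_window_count == 1


def test_borderline_cluster_and_window_matches_oracle():
    recs = [_rec(5000 + i * 600) for i in range(6)] + [_rec(100_000 + i * 9000) for i in range(4)]
    cand = CandidateMicSeq("c", "A" * 100, anchor_records=recs)
    assert anchor_cluster_filter(cand, CFG)
    cl = cand.anchor_cluster
    assert cl.in_window_count == 6 and cl.total_count == 10
    start, count = anchor_window_oracle([r.anchor_pos for r in recs], CFG.cluster_window)
    assert (cl.window_start, cl.in_window_count) == (start, count)


def test_cluster_window_equals_brute_force_on_random_inputs():
    rng = random.Random(11)
    for _ in range(50):
        positions = sorted(rng.randrange(0, 200_000) for _ in range(rng.randrange(2, 60)))
        recs = [_rec(p, pid=f"p{i}") for i, p in enumerate(positions)]
        cl = find_anchor_cluster(recs, CFG.cluster_window)
        start, count = anchor_window_oracle(positions, CFG.cluster_window)
        assert (cl.window_start, cl.in_window_count) == (start, count)


def test_duplicate_pair_ids_count_once():
    recs = [_rec(1000, pid="dup") for _ in range(5)] + [_rec(90_000, pid="far")]
    cl = find_anchor_cluster(recs, CFG.cluster_window)
    assert cl.total_count == 2 and cl.in_window_count == 1


def test_multichromosome_anchors_dilute_the_fraction():
    recs = [_rec(1000 + i, chrom="chr1", pid=f"a{i}") for i in range(4)]
    recs += [_rec(500, chrom="chr2", pid=f"b{i}") for i in range(3)]
    cl = find_anchor_cluster(recs, CFG.cluster_window)
    assert cl.chrom == "chr1"
    assert cl.in_window_count == 4 and cl.total_count == 7


def test_local_reference_filter_rejects_local_copies(reference, jit_warm):
    seg = reference["chr1"][20_000:20_300]
    cand = CandidateMicSeq("c", seg, anchor_records=[_rec(20_000 + i * 100) for i in range(8)])
    assert anchor_cluster_filter(cand, CFG)
    assert not local_reference_filter(cand, reference, CFG)
    novel = CandidateMicSeq(
        "n", random_dna(random.Random(12), 300),
        anchor_records=[_rec(20_000 + i * 100) for i in range(8)],
    )
    assert anchor_cluster_filter(novel, CFG)
    assert local_reference_filter(novel, reference, CFG)


def test_local_reference_pad_clips_at_chromosome_start(reference, jit_warm):
    cand = CandidateMicSeq(
        "edge", random_dna(random.Random(13), 200),
        anchor_records=[_rec(i * 40) for i in range(8)],
    )
    assert anchor_cluster_filter(cand, CFG)
    assert local_reference_filter(cand, reference, CFG)  # no error at the edge


def test_contaminant_screen(jit_warm):
    from micseq.formats import read_fasta
    from importlib import resources

    ref = resources.files("micseq.data").joinpath("synthetic_contaminant.fa")
    with resources.as_file(ref) as path:
        contaminants = read_fasta(path)
    viral = CandidateMicSeq("v", contaminants[0][1][200:500])
    assert not contaminant_filter(viral, contaminants, CFG)
    clean = CandidateMicSeq("r", random_dna(random.Random(14), 300))
    assert contaminant_filter(clean, contaminants, CFG)
    skipped = CandidateMicSeq("s", "ACGT" * 50)
    assert contaminant_filter(skipped, None, CFG)
    assert skipped.filter_trail == [("contaminant", "pass", "skipped")]


def test_filter_chain_order_and_single_application(reference, jit_warm):
    rng = random.Random(15)
    seq = random_dna(rng, 300)
    recs = [_rec(30_000 + i * 100, seq=seq[i : i + 50], pid=f"p{i}") for i in range(8)]
    cand = CandidateMicSeq("good", seq)
    survivors = run_filter_chain([cand], reference, recs, CFG)
    assert survivors == [cand]
    names = [n for n, _, _ in cand.filter_trail]
    assert names == ["known_lowcomplexity", "anchor_cluster", "local_reference", "contaminant"]
    assert len(names) == len(set(names))


def test_attach_anchor_records_uses_read_mapping(reference):
    rng = random.Random(16)
    seq = random_dna(rng, 300)
    supporting = [_rec(1000 + i, seq=seq[i * 20 : i * 20 + 60], pid=f"s{i}") for i in range(5)]
    unrelated = [_rec(2000 + i, seq=random_dna(rng, 60), pid=f"u{i}") for i in range(5)]
    cand = CandidateMicSeq("c", seq)
    attach_anchor_records(cand, supporting + unrelated, CFG)
    assert sorted(r.pair_id for r in cand.anchor_records) == [f"s{i}" for i in range(5)]
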
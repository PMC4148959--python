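"""Simulator: genotype sampling, read arithmetic, determinism, OEA geometry."""

import math

import numpy as np
import pytest

from micseq.dnautil import CODE_TO_BASE, revcomp
from micseq.oea import PairClass, classify_pair
from micseq.simulate import (
    InsertionSpec,
    SimConfig,
    make_population,
    pair_stream,
    simulate_individual,
    write_cohort,
)


def test_zero_insertions_reads_come_from_reference():
    cfg = SimConfig(ref_len=20_000, n_individuals={"AFR": 2}, base_error_rate=0.0, seed=1)
    pop = make_population(cfg)
    ref = pop.reference["chr1"]
    for idx in range(2):
        for blk in simulate_individual(pop, idx):
            assert blk.mapped1.all() and blk.mapped2.all()
            for row in blk.mate1[:20]:
                assert CODE_TO_BASE[row].tobytes().decode() in ref
            for row in blk.mate2[:20]:
                assert revcomp(CODE_TO_BASE[row].tobytes().decode()) in ref


def test_frequency_one_makes_every_genotype_two():
    cfg = SimConfig(
        ref_len=30_000, n_individuals={"AFR": 10, "EUR": 10},
        insertions=[InsertionSpec(length=300, freq=1.0)], seed=2,
    )
    pop = make_population(cfg)
    assert all(g == 2 for g in pop.truth.insertions[0].genotypes.values())


def test_population_private_insertion_stays_private():
    cfg = SimConfig(
        ref_len=30_000, n_individuals={"AFR": 10, "EUR": 10},
        insertions=[InsertionSpec(length=300, freq=0.8, populations=("AFR",))], seed=3,
    )
    pop = make_population(cfg)
    truth = pop.truth.insertions[0]
    for ind in pop.individuals:
        if ind.population == "EUR":
            assert truth.genotypes[ind.sample_id] == 0


def test_realized_allele_frequency_tracks_binomial_sampling():
    """Across seeds, the realized frequency stays within 3 SE of the target."""
    target = 0.3
    n_ind = 200
    se = math.sqrt(target * (1 - target) / (2 * n_ind))
    for seed in range(1, 21):
        cfg = SimConfig(
            ref_len=25_000, n_individuals={"AFR": n_ind},
            insertions=[InsertionSpec(length=200, freq=target)], seed=seed,
        )
        pop = make_population(cfg)
        realized = pop.truth.insertions[0].realized_allele_freq
        assert abs(realized - target) <= 3 * se


def test_read_pair_count_matches_coverage_arithmetic():
    cfg = SimConfig(ref_len=100_000, n_individuals={"AFR": 1}, coverage=4.0, seed=4)
    pop = make_population(cfg)
    n_pairs = sum(len(blk.pair_ids) for blk in simulate_individual(pop, 0))
    expected = 4.0 * 100_000 / (2 * 100)
    assert abs(n_pairs - expected) / expected < 0.05


def test_error_free_reads_are_exact_haplotype_substrings():
    cfg = SimConfig(
        ref_len=20_000, n_individuals={"AFR": 1}, base_error_rate=0.0,
        insertions=[InsertionSpec(length=300, freq=1.0)], seed=5,
    )
    pop = make_population(cfg)
    t = pop.truth.insertions[0]
    hap = pop.reference["chr1"][: t.locus] + t.seq + pop.reference["chr1"][t.locus :]
    for blk in simulate_individual(pop, 0):
        for row in blk.mate1[:50]:
            assert CODE_TO_BASE[row].tobytes().decode() in hap


def test_identical_seed_gives_byte_identical_fastq(tmp_path):
    cfg = SimConfig(
        ref_len=15_000, n_individuals={"AFR": 2},
        insertions=[InsertionSpec(length=200, freq=0.5)], seed=6,
    )
    for run in ("a", "b"):
        write_cohort(make_population(cfg), tmp_path / run)
    for name in ("ref.fa", "AFR000_1.fastq", "AFR000_2.fastq", "AFR001_1.fastq", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_insertion_sequences_are_novel_and_complexity_normal():
    from micseq.dnautil import dust_fraction

    cfg = SimConfig(
        ref_len=40_000, n_individuals={"AFR": 1},
        insertions=[InsertionSpec(length=400, freq=1.0)], seed=7,
    )
    pop = make_population(cfg)
    t = pop.truth.insertions[0]
    assert dust_fraction(t.seq) <= 0.5
    assert t.seq not in pop.reference["chr1"]


def test_overlapping_loci_rejected():
    cfg = SimConfig(
        ref_len=30_000, n_individuals={"AFR": 1},
        insertions=[
            InsertionSpec(length=200, freq=0.5, locus=10_000),
            InsertionSpec(length=200, freq=0.5, locus=12_000),
        ],
        seed=8,
    )
    with pytest.raises(ValueError, match="closer"):
        make_population(cfg)


def test_pair_inside_long_insertion_is_full_orphan_and_boundary_pair_is_oea():
    cfg = SimConfig(
        ref_len=30_000, n_individuals={"AFR": 1},
        insertions=[InsertionSpec(length=500, freq=1.0)], seed=9,
    )
    pop = make_population(cfg)
    classes = {PairClass.OEA: 0, PairClass.FULL_ORPHAN: 0, PairClass.CONCORDANT: 0}
    for pair, a1, a2 in pair_stream(pop, 0):
        cls = classify_pair(a1, a2)
        if cls in classes:
            classes[cls] += 1
    assert classes[PairClass.OEA] > 0
    assert classes[PairClass.FULL_ORPHAN] > 0
    counted = pop.truth.pair_classes["AFR000"]
    assert counted["oea"] == classes[PairClass.OEA]
    assert counted["full_orphan"] == classes[PairClass.FULL_ORPHAN]


def _oea_probability_oracle(cfg: SimConfig, ins_len: int, locus: int) -> float:
    """Exact per-fragment OEA probability by enumeration over (insert, start).

    Integrates the ideal-aligner geometry directly — independent of the
    simulator's vectorized bookkeeping — weighting every rounded insert size
    by its truncated-Normal probability.
    """
    from scipy.stats import norm

    rl = cfg.read_len
    hap_len = cfg.ref_len + ins_len
    lo = 2 * rl
    hi = int(cfg.insert_mean + 5 * cfg.insert_sd)
    sizes = np.arange(lo, hi + 1)
    p_size = norm.cdf(sizes + 0.5, cfg.insert_mean, cfg.insert_sd) - norm.cdf(
        sizes - 0.5, cfg.insert_mean, cfg.insert_sd
    )
    p_size[0] += norm.cdf(lo - 0.5, cfg.insert_mean, cfg.insert_sd)
    p_size[-1] += 1 - norm.cdf(hi + 0.5, cfg.insert_mean, cfg.insert_sd)

    def unmapped(a, b):
        ins_bases = np.maximum(0, np.minimum(b, locus + ins_len) - np.maximum(a, locus))
        return (rl - ins_bases) / rl < cfg.map_ref_frac

    total = 0.0
    for size, p in zip(sizes, p_size):
        s = np.arange(0, hap_len - size + 1)
        u1 = unmapped(s, s + rl)
        u2 = unmapped(s + size - rl, s + size)
        total += p * np.count_nonzero(u1 != u2) / len(s)
    return float(total)


def test_oea_count_matches_geometric_expectation():
    """Mean OEA count over seeds sits within 3 SE of the exact geometry."""
    base = dict(ref_len=30_000, n_individuals={"AFR": 10}, base_error_rate=0.0)
    counts = []
    pairs_per_seed = 0
    for seed in range(1, 11):
        cfg = SimConfig(
            insertions=[InsertionSpec(length=400, freq=1.0, locus=15_000)], seed=seed, **base
        )
        pop = make_population(cfg)
        total = 0
        pairs_per_seed = 0
        for idx in range(10):
            for blk in simulate_individual(pop, idx):
                pairs_per_seed += len(blk.pair_ids)
            total += pop.truth.pair_classes[pop.individuals[idx].sample_id]["oea"]
        counts.append(total)
    cfg0 = SimConfig(insertions=[InsertionSpec(length=400, freq=1.0, locus=15_000)], seed=1, **base)
    p = _oea_probability_oracle(cfg0, ins_len=400, locus=15_000)
    expected = p * pairs_per_seed
    se_mean = math.sqrt(p * (1 - p) * pairs_per_seed) / math.sqrt(len(counts))
    assert abs(np.mean(counts) - expected) <= 3 * se_mean
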
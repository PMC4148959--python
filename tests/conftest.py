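"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (quadratic DP, per-window scans, direct
enumeration) and independent of the implementation paths they check.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from micseq.dnautil import revcomp


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def reads_from_source(
    rng: random.Random,
    source: str,
    read_len: int,
    base_coverage: float,
    mixed_orientation: bool = True,
) -> list[str]:
    """Error-free reads uniformly covering ``source`` at ~base_coverage."""
    n = int(base_coverage * len(source) / read_len)
    out = []
    for _ in range(n):
        s = rng.randrange(0, len(source) - read_len + 1)
        rd = source[s : s + read_len]
        if mixed_orientation and rng.random() < 0.5:
            rd = revcomp(rd)
        out.append(rd)
    return out


# ---------------------------------------------------------------- oracles


def trim_cut_oracle(qual, window: int, min_mean: float) -> int:
    """Evaluate every window mean independently; first failing window wins."""
    n = len(qual)
    for i in range(n):
        win = qual[i : min(i + window, n)]
        if sum(win) / len(win) < min_mean:
            return i
    return n


def kmer_count_oracle(reads, k: int) -> dict[str, int]:
    """Brute-force canonical k-mer counter."""
    counts: dict[str, int] = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            km = read[i : i + k]
            if "N" in km:
                continue
            canon = min(km, revcomp(km))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def sw_score_oracle(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2) -> int:
    """Plain-Python affine-gap Smith-Waterman score (no traceback)."""
    m, n = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def anchor_window_oracle(positions, window: int) -> tuple[int, int]:
    """O(n^2): (leftmost best window start, count) over anchor positions."""
    positions = sorted(positions)
    best_start, best_count = positions[0], 0
    for p in positions:
        count = sum(1 for q in positions if p <= q < p + window)
        if count > best_count:
            best_start, best_count = p, count
    return best_start, best_count


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher test."""
    row1, row2 = a + b, c + d
    col1 = a + c
    N = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == N:
        return 1.0

    def prob(x):
        return (
            math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(N, col1)
        )

    p_obs = prob(a)
    lo, hi = max(0, col1 - row2), min(col1, row1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def coverage_oracle(spans, length: int) -> np.ndarray:
    """Interval-stabbing coverage counter."""
    cov = np.zeros(length, dtype=int)
    for s, e in spans:
        cov[s:e] += 1
    return cov


@pytest.fixture(scope="session")
def jit_warm():
    """Compile the Smith-Waterman kernel once so timings stay honest."""
    from micseq.align import smith_waterman

    smith_waterman("ACGTACGTACGT", "ACGTACGTACGT")
    return True
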
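"""Local alignment machinery: Smith-Waterman, e-values, seed indexing.

This backs three distinct uses in the pipeline:

* the contig-vs-contig similarity graph (full affine-gap Smith-Waterman with
  a Karlin-Altschul e-value on the score),
* reference / local-reference / contaminant screens (seed-and-extend: exact
  15-mer seeds locate the region, Smith-Waterman scores it),
* orphan/evidence read mapping onto a micSeq (exact seed + ungapped
  extension; see :mod:`micseq.annotate`).

The O(mn) fill and traceback are jit-compiled with numba; sequences are
uint8 code arrays from :func:`micseq.dnautil.encode`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .dnautil import encode, revcomp

__all__ = ["Scoring", "AlignmentResult", "smith_waterman", "karlin_lambda", "evalue", "SeedIndex"]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5  # cost of the first gapped base
    gap_extend: int = -2


@dataclass(slots=True)
class AlignmentResult:
    score: int
    identity: float  # matches / alignment columns
    aln_len: int  # alignment columns including gaps
    a_start: int
    a_end: int  # half-open span on sequence a
    b_start: int
    b_end: int
    evalue: float = math.inf


@njit(cache=True)
def _sw(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jit
    m, n = a.shape[0], b.shape[0]
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), NEG, np.int64)
    F = np.full((m + 1, n + 1), NEG, np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            t = E[i, j - 1] + gap_extend
            if t > e:
                e = t
            f = H[i - 1, j] + gap_open
            t = F[i - 1, j] + gap_extend
            if t > f:
                f = t
            s = match if ai == b[j - 1] else mismatch
            v = H[i - 1, j - 1] + s
            if e > v:
                v = e
            if f > v:
                v = f
            if v < 0:
                v = 0
            H[i, j] = v
            E[i, j] = e
            F[i, j] = f
            if v > best:
                best, bi, bj = v, i, j
    # traceback from (bi, bj): states 0=M, 1=E (gap in a), 2=F (gap in b)
    i, j = bi, bj
    matches = 0
    aln_len = 0
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                if a[i - 1] == b[j - 1]:
                    matches += 1
                aln_len += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:
            aln_len += 1
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
    return best, matches, aln_len, i, bi, j, bj


def smith_waterman(a: str, b: str, scoring: Scoring = Scoring()) -> AlignmentResult:
    """Best local alignment of two DNA strings under affine-gap scoring."""
    if not a or not b:
        raise ValueError("empty sequence")
    score, matches, aln_len, a0, a1, b0, b1 = _sw(
        encode(a), encode(b), scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    ident = matches / aln_len if aln_len else 0.0
    return AlignmentResult(
        score=int(score), identity=float(ident), aln_len=int(aln_len),
        a_start=int(a0), a_end=int(a1), b_start=int(b0), b_end=int(b1),
    )


@lru_cache(maxsize=None)
def karlin_lambda(match: int, mismatch: int) -> float:
    """Karlin-Altschul lambda for match/mismatch scoring, uniform bases.

    Solves  (1/4) e^(lambda*match) + (3/4) e^(lambda*mismatch) = 1  for the
    unique positive root; requires a negative expected score per aligned pair.
    """
    expected = 0.25 * match + 0.75 * mismatch
    if expected >= 0:
        raise ValueError("scoring must have negative expectation")

    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 50.0))


#: Order-one Karlin-Altschul K.  The similarity-graph edge criterion
#: (E < 1e-10) is dominated by exp(-lambda*S): genuinely similar contigs sit
#: many orders of magnitude below it and unrelated pairs many above, so a
#: fixed order-one constant changes no decision (see docs/methods.md).
KARLIN_K = 0.3


def evalue(score: int, m: int, n: int, scoring: Scoring = Scoring()) -> float:
    """Expected number of chance local alignments scoring >= ``score``."""
    lam = karlin_lambda(scoring.match, scoring.mismatch)
    try:
        return KARLIN_K * m * n * math.exp(-lam * score)
    except OverflowError:
        return math.inf


class SeedIndex:
    """Exact k-mer index of one subject sequence (forward strand).

    Queries are matched on both strands by also probing the query's reverse
    complement.  ``offsets`` buckets seed hits by alignment diagonal, the
    input to ungapped extension; ``hit_positions`` returns raw subject
    coordinates for seed-and-extend screening.
    """

    def __init__(self, subject: str, seed_len: int = 15):
        self.subject = subject
        self.seed_len = seed_len
        self.codes = encode(subject)
        idx: dict[str, list[int]] = {}
        for i in range(len(subject) - seed_len + 1):
            km = subject[i : i + seed_len]
            if "N" in km:
                continue
            idx.setdefault(km, []).append(i)
        self._idx = idx

    def seed_positions(self, query: str) -> list[tuple[int, int]]:
        """(query_pos, subject_pos) for every exact seed match (forward)."""
        k = self.seed_len
        out = []
        for i in range(len(query) - k + 1):
            hits = self._idx.get(query[i : i + k])
            if hits:
                for j in hits:
                    out.append((i, j))
        return out

    def diagonal_offsets(self, query: str, max_offsets: int = 8) -> list[int]:
        """Distinct subject-minus-query diagonals, most seed-supported first."""
        counts: dict[int, int] = {}
        for i, j in self.seed_positions(query):
            d = j - i
            counts[d] = counts.get(d, 0) + 1
        ranked = sorted(counts, key=lambda d: (-counts[d], d))
        return ranked[:max_offsets]

    def ungapped_hit(
        self, query: str, min_identity: float = 0.95, both_strands: bool = True
    ) -> Optional[tuple[str, int, int, float]]:
        """Best ungapped placement of ``query`` on the subject.

        Tries each seed-supported diagonal; on a diagonal the overlap is
        compared base-by-base (vectorized).  Returns (strand, subject_start,
        subject_end, identity) of the best diagonal with identity >=
        min_identity over the full overlap, or None.
        """
        best = None
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            q = query if strand == "+" else revcomp(query)
            qc = encode(q)
            for d in self.diagonal_offsets(q):
                s0 = max(0, d)
                s1 = min(len(self.subject), d + len(q))
                if s1 <= s0:
                    continue
                q0, q1 = s0 - d, s1 - d
                overlap = s1 - s0
                matches = int(np.count_nonzero(self.codes[s0:s1] == qc[q0:q1]))
                ident = matches / overlap
                if ident >= min_identity and (best is None or ident > best[3]):
                    best = (strand, s0, s1, ident)
        return best
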
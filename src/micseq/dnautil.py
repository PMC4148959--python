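"""Low-level DNA helpers shared across the pipeline.

Everything here operates on plain upper-case strings over {A,C,G,T,N} or on
numpy uint8 code arrays (A=0, C=1, G=2, T=3).  No module in the package keeps
a second convention.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"

# code <-> base lookup used by the simulator and the aligner
CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_BASE_TO_CODE[ord("N")] = 4


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for N-free code arrays."""
    return CODE_TO_BASE[codes].tobytes().decode("ascii")


def canonical(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement.

    With odd k a k-mer is never its own reverse complement, so the choice is
    always strict.
    """
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int):
    """Yield every k-mer of ``seq`` that is free of N."""
    n = len(seq)
    if n < k:
        return
    # fast path: no N anywhere
    if "N" not in seq:
        for i in range(n - k + 1):
            yield seq[i : i + k]
        return
    for i in range(n - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            yield km


def dust_mask(seq: str, window: int = 64, threshold: float = 2.0) -> np.ndarray:
    """DUST-style low-complexity mask.

    Slides a ``window``-nt window over the sequence; within each window the
    triplet-frequency score is  sum_t c_t*(c_t-1)/2 / (n_triplets - 1).  Windows
    scoring above ``threshold`` mask every position they cover.  A perfect
    dinucleotide repeat scores ~15, random sequence ~0.5.

    Returns a boolean array, True where masked.
    """
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    if n < 3:
        return mask
    w = min(window, n)
    # triplet ids; N-containing triplets get id -1 and never count
    codes = encode(seq).astype(np.int64)
    trip = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
    trip[(codes[:-2] > 3) | (codes[1:-1] > 3) | (codes[2:] > 3)] = -1
    counts = np.zeros(64, dtype=np.int64)
    score_num = 0  # sum c*(c-1)/2 over triplets present
    n_trip_in_window = w - 2
    denom = max(n_trip_in_window - 1, 1)

    def _add(t):
        nonlocal score_num
        if t >= 0:
            score_num += counts[t]
            counts[t] += 1

    def _remove(t):
        nonlocal score_num
        if t >= 0:
            counts[t] -= 1
            score_num -= counts[t]

    for j in range(n_trip_in_window):
        _add(trip[j])
    if score_num / denom > threshold:
        mask[0:w] = True
    for start in range(1, n - w + 1):
        _remove(trip[start - 1])
        _add(trip[start + n_trip_in_window - 1])
        if score_num / denom > threshold:
            mask[start : start + w] = True
    return mask


def dust_fraction(seq: str, window: int = 64, threshold: float = 2.0) -> float:
    """Fraction of positions masked by :func:`dust_mask`."""
    if not seq:
        return 0.0
    return float(dust_mask(seq, window, threshold).mean())
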
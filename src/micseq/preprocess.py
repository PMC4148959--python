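"""Sliding-window quality trimming of read pairs.

A read is scanned 5'->3' with a sliding window (default 4 nt).  At the first
window whose mean Phred quality drops below the threshold (default 25) the
read is truncated at that window's first base.  Reads left shorter than the
minimum length (default 20 nt) are dropped, and dropping either mate drops
the whole pair.  Trailing windows shorter than the window size are evaluated
on their actual length.  Trimming is 3'-only: the retained part is always a
prefix of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .formats import ReadPair

__all__ = ["TrimConfig", "trim_read", "trim_pair", "trim_pairs", "TrimStats"]


@dataclass(slots=True)
class TrimConfig:
    window: int = 4
    min_mean_qual: float = 25.0
    min_len: int = 20

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


def trim_read(
    seq: str, qual: np.ndarray, cfg: TrimConfig = TrimConfig()
) -> Optional[tuple[str, np.ndarray]]:
    """Trim one read; returns (seq, qual) or None when the read is dropped."""
    n = len(seq)
    if n == 0:
        return None
    qual = np.asarray(qual)
    cut = _cut_index(qual, cfg.window, cfg.min_mean_qual)
    if cut < cfg.min_len:
        return None
    return seq[:cut], qual[:cut]


def _cut_index(qual: np.ndarray, window: int, min_mean: float) -> int:
    """Index of the first base of the first failing window, or len(qual)."""
    n = len(qual)
    if qual.min() >= min_mean:  # no window can fail
        return n
    cs = np.concatenate(([0], np.cumsum(qual, dtype=np.int64)))
    ends = np.minimum(np.arange(n) + window, n)
    sums = cs[ends] - cs[:n]
    lens = ends - np.arange(n)
    bad = np.nonzero(sums < min_mean * lens)[0]
    return int(bad[0]) if bad.size else n


def trim_pair(pair: ReadPair, cfg: TrimConfig = TrimConfig()) -> Optional[ReadPair]:
    """Trim both mates; if either mate is dropped the whole pair is dropped."""
    r1 = trim_read(pair.mate1_seq, pair.mate1_qual, cfg)
    if r1 is None:
        return None
    r2 = trim_read(pair.mate2_seq, pair.mate2_qual, cfg)
    if r2 is None:
        return None
    return ReadPair(
        pair_id=pair.pair_id,
        mate1_seq=r1[0],
        mate1_qual=r1[1],
        mate2_seq=r2[0],
        mate2_qual=r2[1],
        sample_id=pair.sample_id,
        population=pair.population,
    )


@dataclass(slots=True)
class TrimStats:
    pairs_in: int = 0
    pairs_kept: int = 0
    pairs_dropped: int = 0
    mates_truncated: int = 0


def trim_pairs(
    pairs: Iterable[ReadPair], cfg: TrimConfig = TrimConfig(), stats: Optional[TrimStats] = None
) -> Iterator[ReadPair]:
    """Stream-trim pairs, optionally accumulating counts into ``stats``."""
    for pair in pairs:
        if stats is not None:
            stats.pairs_in += 1
        trimmed = trim_pair(pair, cfg)
        if trimmed is None:
            if stats is not None:
                stats.pairs_dropped += 1
            continue
        if stats is not None:
            stats.pairs_kept += 1
            if len(trimmed.mate1_seq) < len(pair.mate1_seq):
                stats.mates_truncated += 1
            if len(trimmed.mate2_seq) < len(pair.mate2_seq):
                stats.mates_truncated += 1
        yield trimmed
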
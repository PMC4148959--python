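"""Population-stratification statistics on micSeq carrier frequencies.

Printed per-population frequencies are turned back into diploid allele
counts (round-half-up of freq * n * ploidy) and each micSeq is tested
African vs pooled non-African with a two-sided Fisher's exact test on the
2x2 allele-present/absent table.  No multiple-testing correction is applied;
significance is reported at the raw alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "FreqTable",
    "Table2x2",
    "reconstruct_counts",
    "fisher_exact_2x2",
    "stratification_report",
    "load_freq_table",
    "validation_freq_table",
]


@dataclass(slots=True)
class Table2x2:
    """Counts: rows group1/group2, columns allele-present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(slots=True)
class FreqTable:
    """Per-micSeq carrier/allele frequencies for EUR / ASN / AFR groups."""

    rows: dict[str, tuple[float, float, float]]  # id -> (freq_EUR, freq_ASN, freq_AFR)
    n_samples: tuple[int, int, int]  # (n_EUR, n_ASN, n_AFR)
    ploidy: int = 2

    def __post_init__(self):
        for mid, freqs in self.rows.items():
            for f in freqs:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"{mid}: frequency {f} outside [0,1]")
        if min(self.n_samples) <= 0:
            raise ValueError("sample sizes must be positive")


def reconstruct_counts(freq: float, n: int, ploidy: int = 2) -> int:
    """Nearest-integer (half-up) allele count implied by a printed frequency."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency {freq} outside [0,1]")
    return int(math.floor(freq * n * ploidy + 0.5))


def fisher_exact_2x2(t: Table2x2) -> float:
    """Two-sided Fisher's exact p-value.

    Standard two-sided rule: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.  Degenerate margins give p = 1.
    """
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        return 1.0
    return float(_scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def stratification_report(tbl: FreqTable, alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Fisher test of African vs pooled non-African allele counts per micSeq.

    Each row reports the reconstructed counts, the two-sided p-value and an
    ``african_max`` flag set when the African frequency strictly exceeds both
    other groups.  The summary counts flagged rows and rows with p < alpha.
    """
    n_eur, n_asn, n_afr = tbl.n_samples
    recs = []
    for mid in tbl.rows:  # insertion-ordered; report is row-order independent
        f_eur, f_asn, f_afr = tbl.rows[mid]
        afr = reconstruct_counts(f_afr, n_afr, tbl.ploidy)
        non_afr = reconstruct_counts(f_eur, n_eur, tbl.ploidy) + reconstruct_counts(
            f_asn, n_asn, tbl.ploidy
        )
        tot_afr = n_afr * tbl.ploidy
        tot_non = (n_eur + n_asn) * tbl.ploidy
        p = fisher_exact_2x2(Table2x2(afr, tot_afr - afr, non_afr, tot_non - non_afr))
        recs.append(
            {
                "micseq_id": mid,
                "freq_eur": f_eur,
                "freq_asn": f_asn,
                "freq_afr": f_afr,
                "afr_alleles": afr,
                "nonafr_alleles": non_afr,
                "p_value": p,
                "african_max": f_afr > f_eur and f_afr > f_asn,
                "significant": p < alpha,
            }
        )
    df = pd.DataFrame.from_records(recs).sort_values("micseq_id").reset_index(drop=True)
    summary = {
        "n_micseqs": len(df),
        "n_african_max": int(df["african_max"].sum()) if len(df) else 0,
        "n_significant": int(df["significant"].sum()) if len(df) else 0,
        "alpha": alpha,
    }
    return df, summary


def load_freq_table(path, n_samples: tuple[int, int, int], ploidy: int = 2) -> FreqTable:
    """Read a TSV with columns micseq_id, freq_eur, freq_asn, freq_afr."""
    df = pd.read_csv(path, sep="\t")
    rows = {
        str(r.micseq_id): (float(r.freq_eur), float(r.freq_asn), float(r.freq_afr))
        for r in df.itertuples()
    }
    return FreqTable(rows=rows, n_samples=n_samples, ploidy=ploidy)


def validation_freq_table() -> FreqTable:
    """The packaged 15-micSeq PCR validation frequency table (n = 14/12/12)."""
    ref = resources.files("micseq.data").joinpath("validation_frequencies.tsv")
    with resources.as_file(ref) as path:
        return load_freq_table(path, n_samples=(14, 12, 12), ploidy=2)
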
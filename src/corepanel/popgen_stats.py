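"""Per-locus population-genetic summaries and SNP density windows.

For a biallelic locus with alt-allele frequency ``p`` (``q = 1 - p``) among
non-missing calls:

* MAF = min(p, q)
* Ho  = heterozygous calls / non-missing calls (observed heterozygosity)
* He  = 2pq (expected heterozygosity, "genetic diversity")
* Pi  = 2pq * n/(n - 1), n = number of non-missing *alleles* (the unbiased
  per-site nucleotide diversity; can slightly exceed 0.5)
* PIC = 1 - (p² + q²) - 2p²q² (Botstein marker informativeness; always
  below He for 0 < p < 1)

All statistics are invariant under swapping which allele is called ref.
Tabular reports round to 3 decimals, half-up.
"""

from __future__ import annotations

import decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, Locus

__all__ = [
    "allele_stats",
    "locus_stats_table",
    "pic",
    "pic_biallelic",
    "summarize_panel",
    "snp_density",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal round-half-up (0.0005 → 0.001), as printed genetics tables do."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _freq_ho(col: np.ndarray) -> tuple[float, float, int]:
    """(alt frequency, observed het, n non-missing calls) for one column."""
    col = np.asarray(col)
    ok = col != MISSING
    n = int(ok.sum())
    if n == 0:
        return np.nan, np.nan, 0
    vals = col[ok]
    p = float(vals.sum()) / (2.0 * n)
    ho = float(np.mean(vals == 1))
    return p, ho, n


def allele_stats(col: np.ndarray) -> tuple[float, float, float, float]:
    """(maf, Ho, He, Pi) for a single genotype-code column.

    Raises if the column is entirely missing (the statistics are undefined).
    """
    p, ho, n = _freq_ho(col)
    if n == 0:
        raise ValueError("allele_stats undefined on an all-missing column")
    he = 2.0 * p * (1.0 - p)
    n_alleles = 2 * n
    pi = he * n_alleles / (n_alleles - 1) if n_alleles > 1 else np.nan
    return min(p, 1.0 - p), ho, he, pi


def pic(freqs: Sequence[float]) -> float:
    """Botstein polymorphic information content for arbitrary allele frequencies.

    PIC = 1 - Σ p_i² - Σ_{i<j} 2 p_i² p_j²
    """
    f = np.asarray(freqs, dtype=float)
    if f.size and not np.isclose(f.sum(), 1.0, atol=1e-8):
        raise ValueError(f"allele frequencies must sum to 1, got {f.sum()}")
    sq = f ** 2
    cross = (sq.sum() ** 2 - (sq ** 2).sum())  # 2 Σ_{i<j} p_i² p_j²
    return float(1.0 - sq.sum() - cross)


def pic_biallelic(p: float) -> float:
    """Closed-form biallelic PIC: 1 - (p² + q²) - 2p²q²."""
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def locus_stats_table(genotypes: np.ndarray, loci: Sequence[Locus] | None = None
                      ) -> pd.DataFrame:
    """Per-locus maf/Ho/He/Pi/PIC table for an n_samples × n_loci code matrix.

    Works on sample-level genotypes and on cultivar-consensus matrices
    alike (a consensus matrix is just a genotype matrix with one row per
    cultivar).  Loci with no non-missing call get NaN throughout.
    """
    G = np.asarray(genotypes)
    ok = G != MISSING
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(ok, G, 0).sum(axis=0)
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        maf = np.minimum(p, 1.0 - p)
        ho = np.where(n > 0, (G == 1).sum(axis=0) / n, np.nan)
        he = 2.0 * p * (1.0 - p)
        n_alleles = 2.0 * n
        pi = np.where(n_alleles > 1, he * n_alleles / (n_alleles - 1.0), np.nan)
        q = 1.0 - p
        pic_col = 1.0 - (p ** 2 + q ** 2) - 2.0 * p ** 2 * q ** 2
    df = pd.DataFrame(
        {"maf": maf, "ho": ho, "he": he, "pi": pi, "pic": pic_col,
         "n_calls": n.astype(int)}
    )
    if loci is not None:
        df.insert(0, "locus", [loc.id for loc in loci])
        df.insert(1, "chrom", [loc.chrom for loc in loci])
        df.insert(2, "pos", [loc.pos for loc in loci])
    return df


def summarize_panel(stats: pd.DataFrame) -> pd.DataFrame:
    """Mean / min / max per statistic column, NaN-excluded.

    Returns a table indexed by statistic with columns mean, min, max.
    """
    cols = [c for c in ("maf", "ho", "he", "pi", "pic") if c in stats.columns]
    if not len(stats):
        raise ValueError("cannot summarize an empty panel")
    rows = {}
    for c in cols:
        v = stats[c].dropna()
        if not len(v):
            rows[c] = (np.nan, np.nan, np.nan)
        else:
            rows[c] = (v.mean(), v.min(), v.max())
    return pd.DataFrame(rows, index=["mean", "min", "max"]).T


def snp_density(loci: Sequence[Locus], window: int = 500_000, step: int = 500_000,
                chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Sliding-window locus counts per chromosome.

    Windows are half-open ``[k*step, k*step + window)`` in 0-based terms,
    i.e. positions 1..window fall in the first window.  With step == window
    the windows tile each chromosome and counts sum to the locus total.
    Chromosome lengths default to the maximum observed position.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    by_chrom: dict[str, list[int]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc.pos)
    if chrom_lengths:
        for chrom in chrom_lengths:
            by_chrom.setdefault(chrom, [])
    rows = []
    for chrom in sorted(by_chrom):
        pos = np.asarray(sorted(by_chrom[chrom]), dtype=np.int64)
        length = (chrom_lengths or {}).get(chrom, int(pos.max()) if pos.size else window)
        n_win = max(1, -(-max(length - window, 0) // step) + 1)
        for k in range(n_win):
            start = k * step  # 0-based half-open [start, start+window)
            count = int(((pos > start) & (pos <= start + window)).sum())
            rows.append((chrom, start + 1, start + window, count))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
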
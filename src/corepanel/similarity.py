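"""Pairwise sample similarity and the core-vs-total correlation validation.

Similarity between two samples over a locus set is the number of loci with
consistent (identical) genotype codes divided by the number of loci where
both samples have a non-missing call.  Heterozygote matching is exact on
codes: a het is consistent only with a het.  A pair with no common loci
has undefined similarity (NaN).

The validation regresses core-panel similarity on total-SNP similarity
over all unordered sample pairs and reports the ordinary least-squares
slope/intercept together with the Pearson correlation and its two-sided
t-test p-value.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["SimilarityMatrix", "CorrelationResult",
           "pairwise_similarity", "similarity_correlation"]


@dataclasses.dataclass
class SimilarityMatrix:
    """Symmetric n × n consistent/common similarity with companion counts."""

    samples: list[str]
    values: np.ndarray       # similarity in [0, 1], NaN where common == 0
    common: np.ndarray       # number of loci non-missing in both samples

    def __post_init__(self) -> None:
        n = len(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        self.common = np.asarray(self.common, dtype=np.int64)
        if self.values.shape != (n, n) or self.common.shape != (n, n):
            raise ValueError("similarity matrices must be n x n")

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) similarities in row-major pair order."""
        iu = np.triu_indices(len(self.samples), k=1)
        return self.values[iu]

    def pair_table(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.samples), k=1)
        return pd.DataFrame({
            "sample_i": [self.samples[i] for i in iu],
            "sample_j": [self.samples[j] for j in ju],
            "similarity": self.values[iu, ju],
            "common": self.common[iu, ju],
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclasses.dataclass
class CorrelationResult:
    """OLS fit of core similarity on total similarity across sample pairs."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n_pairs: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self))
        if path is not None:
            Path(path).write_text(text)
        return text


def pairwise_similarity(gm: GenotypeMatrix,
                        loci_indices: Sequence[int] | None = None
                        ) -> SimilarityMatrix:
    """Consistent/common similarity for every sample pair over a locus subset."""
    if loci_indices is None:
        geno = gm.genotypes
    else:
        idx = np.asarray(loci_indices, dtype=np.intp)
        if idx.size == 0:
            raise ValueError("locus subset must be non-empty")
        geno = gm.genotypes[:, idx]
    if geno.shape[1] == 0:
        raise ValueError("locus subset must be non-empty")
    V = (geno != MISSING)
    common = (V.astype(np.int64) @ V.T.astype(np.int64))
    consistent = np.zeros_like(common)
    for c in (0, 1, 2):
        I = (geno == c).astype(np.int64)
        consistent += I @ I.T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = consistent / common
    values[common == 0] = np.nan
    return SimilarityMatrix(samples=list(gm.samples), values=values, common=common)


def similarity_correlation(total_sim: SimilarityMatrix,
                           core_sim: SimilarityMatrix) -> CorrelationResult:
    """Pearson r, p and OLS line between core and total pair similarities.

    Self-pairs (the diagonal) are excluded; pairs undefined in either
    matrix are dropped.  Requires ≥ 3 defined pairs and non-degenerate
    variance in both vectors.
    """
    if total_sim.samples != core_sim.samples:
        raise ValueError("similarity matrices must cover the same samples in order")
    x = total_sim.condensed()
    y = core_sim.condensed()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 defined pairs, got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("similarity vector has zero variance; r undefined")
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=int(x.size),
    )
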
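"""The six-stage core-SNP screening cascade.

Starting from a depth-filtered, biallelic SNP matrix, the cascade

1. masks low-depth calls (depth must exceed ``min_depth``) and drops
   non-biallelic loci ("total SNPs");
2. collapses samples to cultivar-consensus genotypes: the modal genotype
   of a cultivar's non-missing calls becomes the cultivar genotype when it
   reaches the identity threshold (default ≥ 70%), otherwise the cultivar
   is recorded missing at that locus;
3. removes loci without polymorphism among cultivar-consensus calls and
   loci failing the Hardy–Weinberg exact test (p < 1e-5) on the pooled
   sample-level genotype counts;
4. removes loci with consensus missingness > 30% or consensus MAF < 0.01;
5. removes loci with consensus PIC < 0.1;
6. prunes residual linkage disequilibrium with a PLINK-style sliding
   window (50 SNPs, step 10, r² > 0.99) on sample-level dosages.

Every stage is also exposed on its own, and :func:`select_core` returns a
:class:`FilterReport` whose per-stage arithmetic is exact (out = in −
removed) together with the surviving core panel.

Threshold boundaries are read literally: depth strictly > 4 retained;
identity ≥ 0.70 inclusive; HWE p strictly < 1e-5 removed; missingness
strictly > 0.30 removed; MAF strictly < 0.01 removed; PIC strictly < 0.1
removed; r² strictly > 0.99 triggers removal.
"""

from __future__ import annotations

import dataclasses
import json
from functools import lru_cache
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix, Locus, VarietyAssignment

__all__ = [
    "FilterParams",
    "FilterReport",
    "ConsensusMatrix",
    "CoreSelection",
    "filter_depth_biallelic",
    "consensus_genotypes",
    "hwe_exact_test",
    "polymorphism_hwe_filter",
    "missing_maf_filter",
    "pic_filter",
    "ld_prune",
    "select_core",
]


@dataclasses.dataclass
class FilterParams:
    """Thresholds of the screening cascade (defaults = the published screen).

    ``hwe_level`` selects the genotype matrix the HWE exact test runs on:
    ``"samples"`` (default) pools all individual genotypes; ``"consensus"``
    uses the cultivar-consensus calls — with 4 cultivars the exact test can
    never reach p < 1e-5, so the consensus setting effectively disables the
    HWE stage and exists for completeness.
    """

    min_depth: int = 4            # calls kept only when depth > min_depth
    identity_threshold: float = 0.70
    hwe_alpha: float = 1e-5
    max_missing: float = 0.30
    min_maf: float = 0.01
    min_pic: float = 0.10
    ld_window: int = 50
    ld_step: int = 10
    ld_r2: float = 0.99
    hwe_level: Literal["samples", "consensus"] = "samples"

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for name in ("identity_threshold", "max_missing", "min_maf", "min_pic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must be in (0, 1)")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise ValueError("ld_r2 must be in [0, 1]")
        if self.ld_step < 1 or self.ld_window < 1 or self.ld_step > self.ld_window:
            raise ValueError("need 1 <= ld_step <= ld_window")
        if self.hwe_level not in ("samples", "consensus"):
            raise ValueError(f"hwe_level must be 'samples' or 'consensus'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ConsensusMatrix:
    """Cultivars × loci consensus genotype codes ({0, 1, 2, MISSING})."""

    varieties: list[str]
    loci: list[Locus]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.varieties), len(self.loci)):
            raise ValueError("consensus shape does not match varieties x loci")

    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, indices: Sequence[int] | np.ndarray) -> "ConsensusMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return ConsensusMatrix(
            varieties=list(self.varieties),
            loci=[self.loci[i] for i in idx],
            genotypes=self.genotypes[:, idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes.T, columns=self.varieties)
        df.insert(0, "locus", [loc.id for loc in self.loci])
        return df


@dataclasses.dataclass
class FilterReport:
    """Audit trail of the cascade: per-stage counts and per-locus reasons.

    Invariant: each stage's loci-out equals the next stage's loci-in and
    removed = in − out, checked at construction time by ``add_stage``.
    """

    stages: list[tuple[str, int, int, int]] = dataclasses.field(default_factory=list)
    removal_reasons: dict[str, str] = dataclasses.field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_out: int,
                  removed_ids: Sequence[str] = (), reason: str | None = None) -> None:
        n_removed = n_in - n_out
        if n_removed < 0:
            raise ValueError(f"stage {name}: out ({n_out}) exceeds in ({n_in})")
        if self.stages and self.stages[-1][3] != n_in:
            raise ValueError(
                f"stage {name}: in ({n_in}) != previous out ({self.stages[-1][3]})"
            )
        self.stages.append((name, n_in, n_removed, n_out))
        for lid in removed_ids:
            self.removal_reasons.setdefault(lid, reason or name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "loci_in", "loci_removed", "loci_out"]
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "stages": [
                {"stage": s, "loci_in": a, "loci_removed": b, "loci_out": c}
                for s, a, b, c in self.stages
            ],
            "removal_reasons": self.removal_reasons,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def filter_depth_biallelic(gm: GenotypeMatrix, params: FilterParams | None = None
                           ) -> tuple[GenotypeMatrix, list[str]]:
    """Stage 1: mask calls with depth ≤ min_depth; keep only biallelic SNPs.

    Returns the filtered matrix and the ids of removed (non-biallelic) loci.
    """
    params = params or FilterParams()
    geno = gm.genotypes.copy()
    geno[gm.depths <= params.min_depth] = MISSING
    keep = [j for j, loc in enumerate(gm.loci) if loc.is_biallelic_snp]
    removed = [gm.loci[j].id for j in range(gm.n_loci)
               if not gm.loci[j].is_biallelic_snp]
    out = GenotypeMatrix(
        samples=list(gm.samples),
        loci=[gm.loci[j] for j in keep],
        genotypes=geno[:, keep],
        depths=gm.depths[:, keep].copy(),
    )
    return out, removed


def consensus_genotypes(gm: GenotypeMatrix, varieties: VarietyAssignment,
                        params: FilterParams | None = None) -> ConsensusMatrix:
    """Stage 2: collapse samples to cultivar-consensus genotypes.

    Per cultivar and locus the modal code among non-missing member calls
    becomes the consensus when its identity rate (modal count / non-missing
    count) reaches ``identity_threshold``; otherwise — and when every call
    is missing — the consensus is MISSING.  With a threshold above 0.5 a
    qualifying mode is unique, so the result does not depend on sample
    order or tie-breaking.
    """
    params = params or FilterParams()
    groups = varieties.group_indices(gm.samples)
    names = list(groups)
    cons = np.full((len(names), gm.n_loci), MISSING, dtype=np.int8)
    for k, name in enumerate(names):
        sub = gm.genotypes[groups[name], :]
        counts = np.stack([(sub == c).sum(axis=0) for c in (0, 1, 2)])  # 3 × m
        n_obs = counts.sum(axis=0)
        modal = counts.argmax(axis=0)
        modal_count = counts.max(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ok = (n_obs >= 1) & (modal_count >= params.identity_threshold * n_obs)
        cons[k, ok] = modal[ok]
    return ConsensusMatrix(varieties=names, loci=list(gm.loci), genotypes=cons)


@lru_cache(maxsize=100_000)
def hwe_exact_components(n_homref: int, n_het: int, n_homalt: int
                         ) -> tuple[float, float]:
    """Tail components of the exact Hardy–Weinberg test.

    Conditional on the observed allele counts, heterozygote counts follow
    the Levene/Haldane distribution.  Returns ``(p_less, p_equal)``: the
    total probability of attainable heterozygote counts strictly less
    likely than the observed one, and of those exactly as likely
    (including the observed count itself).  The standard two-sided exact
    p-value is ``p_less + p_equal``; the mid-p variant is
    ``p_less + p_equal/2``; a randomized (fuzzy) p-value uniform under the
    null is ``p_less + U * p_equal``.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        return 0.0, 1.0
    n_a = 2 * n_homref + n_het      # reference allele count
    n_b = 2 * n_homalt + n_het
    rare = min(n_a, n_b)
    # attainable heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2       # rare-allele homozygotes
    homc = n - hets - homr
    # log P(het) ∝ het*log2 - log(het!) - log(homr!) - log(homc!)
    logp = (hets * np.log(2.0) - gammaln(hets + 1.0)
            - gammaln(homr + 1.0) - gammaln(homc + 1.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[(hets == n_het).argmax()]
    # relative epsilon groups exact ties (symmetric configurations) together
    eq = probs[np.abs(probs - p_obs) <= p_obs * 1e-9]
    less = probs[probs < p_obs * (1.0 - 1e-9)]
    return float(less.sum()), float(min(1.0, eq.sum()))


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value from genotype counts.

    Sums, over all heterozygote counts consistent with the observed allele
    counts, the Levene/Haldane conditional probabilities not exceeding the
    observed configuration's.  Total count 0 returns 1 by convention.
    """
    less, eq = hwe_exact_components(n_homref, n_het, n_homalt)
    return float(min(1.0, less + eq))


def _pooled_counts(geno: np.ndarray) -> np.ndarray:
    """3 × m table of (hom-ref, het, hom-alt) counts over rows."""
    return np.stack([(geno == c).sum(axis=0) for c in (0, 1, 2)])


def polymorphism_hwe_filter(cm: ConsensusMatrix, gm: GenotypeMatrix,
                            params: FilterParams | None = None
                            ) -> tuple[ConsensusMatrix, dict[str, str]]:
    """Stage 3: drop non-polymorphic loci and HWE-violating loci.

    A locus is non-polymorphic when its non-missing consensus calls are all
    identical (all-missing counts as non-polymorphic too).  The HWE exact
    test runs at ``params.hwe_level``: pooled sample genotypes by default.
    Returns the filtered consensus and a locus-id → reason mapping.
    """
    params = params or FilterParams()
    if [l.id for l in cm.loci] != [l.id for l in gm.loci]:
        raise ValueError("consensus and genotype matrices must share loci")
    cons = cm.genotypes
    ok = cons != MISSING
    n_obs = ok.sum(axis=0)
    first = np.where(ok, cons, MISSING).max(axis=0)  # some non-missing value
    all_same = np.ones(cm.n_loci, dtype=bool)
    for c in (0, 1, 2):
        has_c = ((cons == c).sum(axis=0) > 0)
        all_same &= ~(has_c & ((cons == c).sum(axis=0) < n_obs))
    # all_same as computed above: no code is present-but-not-universal
    polymorphic = (n_obs > 0) & ~all_same
    del first

    hwe_geno = gm.genotypes if params.hwe_level == "samples" else cons
    counts = _pooled_counts(hwe_geno)
    pvals = np.array([
        hwe_exact_test(int(a), int(b), int(c)) for a, b, c in counts.T
    ]) if cm.n_loci else np.zeros(0)

    reasons: dict[str, str] = {}
    keep = []
    for j, loc in enumerate(cm.loci):
        if not polymorphic[j]:
            reasons[loc.id] = "non_polymorphic"
        elif pvals[j] < params.hwe_alpha:
            reasons[loc.id] = "hwe"
        else:
            keep.append(j)
    return cm.subset_loci(keep), reasons


def consensus_maf(cm: ConsensusMatrix) -> np.ndarray:
    """Per-locus minor-allele frequency over consensus calls (2 alleles each)."""
    ok = cm.genotypes != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, cm.genotypes, 0).sum(axis=0) / (2.0 * n)
    return np.where(n > 0, np.minimum(p, 1.0 - p), np.nan)


def missing_maf_filter(cm: ConsensusMatrix, params: FilterParams | None = None
                       ) -> tuple[ConsensusMatrix, dict[str, str]]:
    """Stage 4: drop loci with consensus missingness > 30% or MAF < 1%."""
    params = params or FilterParams()
    miss = (cm.genotypes == MISSING).mean(axis=0) if cm.n_varieties else np.zeros(cm.n_loci)
    maf = consensus_maf(cm)
    reasons: dict[str, str] = {}
    keep = []
    for j, loc in enumerate(cm.loci):
        if miss[j] > params.max_missing:
            reasons[loc.id] = "missingness"
        elif not (maf[j] >= params.min_maf):  # NaN maf (all missing) removed too
            reasons[loc.id] = "maf"
        else:
            keep.append(j)
    return cm.subset_loci(keep), reasons


def pic_filter(cm: ConsensusMatrix, params: FilterParams | None = None
               ) -> tuple[ConsensusMatrix, dict[str, str]]:
    """Stage 5: drop loci whose consensus-frequency PIC is below min_pic."""
    params = params or FilterParams()
    maf = consensus_maf(cm)
    with np.errstate(invalid="ignore"):
        p = maf
        q = 1.0 - p
        pic = 1.0 - (p ** 2 + q ** 2) - 2.0 * p ** 2 * q ** 2
    reasons: dict[str, str] = {}
    keep = []
    for j, loc in enumerate(cm.loci):
        if pic[j] >= params.min_pic:
            keep.append(j)
        else:
            reasons[loc.id] = "pic"
    return cm.subset_loci(keep), reasons


def _sample_maf(geno: np.ndarray) -> np.ndarray:
    ok = geno != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, geno, 0).sum(axis=0) / (2.0 * n)
    return np.where(n > 0, np.minimum(p, 1.0 - p), 0.0)


def _window_r2(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation of dosage columns.

    ``X`` is samples × w with MISSING sentinels.  Pairs with fewer than two
    complete observations or zero variance get r² = 0.
    """
    V = (X != MISSING).astype(float)
    X0 = np.where(X == MISSING, 0, X).astype(float)
    n = V.T @ V                        # complete-pair counts
    sx = X0.T @ V                      # Σ x_j over pairs complete in (j, k)
    sxx = (X0 ** 2).T @ V
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_j = sxx - sx ** 2 / n      # var of column j over the (j,k) pairs
        r2 = cov ** 2 / (var_j * var_j.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(gm: GenotypeMatrix, loci_indices: Sequence[int] | None = None,
             params: FilterParams | None = None) -> list[int]:
    """Stage 6: sliding-window LD pruning of sample-level dosages.

    Windows of ``ld_window`` SNPs advance by ``ld_step`` along each
    chromosome (in position order).  Within a window, pairs are scanned in
    order; when a retained pair exceeds ``ld_r2`` the member with the lower
    sample-level MAF is removed (tie → the later locus).  Returns the
    retained positions *within* ``loci_indices`` (indices into ``gm.loci``).
    """
    params = params or FilterParams()
    if loci_indices is None:
        loci_indices = list(range(gm.n_loci))
    idx = np.asarray(loci_indices, dtype=np.intp)
    if idx.size == 0:
        return []
    geno = gm.genotypes[:, idx]
    maf = _sample_maf(geno)
    chroms = np.array([gm.loci[i].chrom for i in idx])
    keep = np.ones(idx.size, dtype=bool)

    for chrom in pd.unique(chroms):
        where = np.flatnonzero(chroms == chrom)
        m = where.size
        start = 0
        while True:
            win = where[start:start + params.ld_window]
            if win.size >= 2:
                r2 = _window_r2(geno[:, win])
                for a in range(win.size):
                    if not keep[win[a]]:
                        continue
                    for b in range(a + 1, win.size):
                        if not keep[win[b]]:
                            continue
                        if r2[a, b] > params.ld_r2:
                            ja, jb = win[a], win[b]
                            if maf[ja] < maf[jb]:
                                keep[ja] = False
                                break  # ja gone; move to next a
                            else:       # lower-MAF or tie → drop the later locus
                                keep[jb] = False
            if start + params.ld_window >= m:
                break
            start += params.ld_step
    return [int(i) for i in idx[np.flatnonzero(keep)]]


@dataclasses.dataclass
class CoreSelection:
    """Result of the full cascade.

    ``total``: depth/biallelic-filtered sample matrix ("total SNPs");
    ``consensus``: consensus matrix of the surviving core loci;
    ``core_indices``: core-locus column indices into ``total``;
    ``report``: per-stage audit trail.
    """

    total: GenotypeMatrix
    consensus: ConsensusMatrix
    core_indices: list[int]
    report: FilterReport
    params: FilterParams

    @property
    def core_loci(self) -> list[Locus]:
        return [self.total.loci[i] for i in self.core_indices]

    @property
    def core_genotypes(self) -> GenotypeMatrix:
        """Sample-level genotype matrix restricted to the core panel."""
        return self.total.subset_loci(self.core_indices)

    @property
    def pic_stage_indices(self) -> list[int]:
        """Column indices (into ``total``) of loci alive after the PIC stage,
        i.e. the core panel plus whatever LD pruning later removed."""
        ld_removed = {lid for lid, r in self.report.removal_reasons.items()
                      if r == "ld"}
        alive = ld_removed | {loc.id for loc in self.consensus.loci}
        return [j for j, loc in enumerate(self.total.loci) if loc.id in alive]


def select_core(gm: GenotypeMatrix, varieties: VarietyAssignment,
                params: FilterParams | None = None) -> CoreSelection:
    """Run the full six-stage screening cascade.

    An empty surviving panel is a valid outcome (complete report retained).
    """
    params = params or FilterParams()
    report = FilterReport()

    total, removed = filter_depth_biallelic(gm, params)
    report.add_stage("depth_biallelic", gm.n_loci, total.n_loci, removed,
                     "non_biallelic")

    cm = consensus_genotypes(total, varieties, params)
    report.add_stage("consensus", total.n_loci, cm.n_loci)

    cm, reasons = polymorphism_hwe_filter(cm, total, params)
    report.add_stage("polymorphism_hwe", report.stages[-1][3], cm.n_loci)
    report.removal_reasons.update(reasons)

    cm, reasons = missing_maf_filter(cm, params)
    report.add_stage("missing_maf", report.stages[-1][3], cm.n_loci)
    report.removal_reasons.update(reasons)

    cm, reasons = pic_filter(cm, params)
    report.add_stage("pic", report.stages[-1][3], cm.n_loci)
    report.removal_reasons.update(reasons)

    alive_ids = {loc.id for loc in cm.loci}
    alive_idx = [j for j, loc in enumerate(total.loci) if loc.id in alive_ids]
    kept_idx = ld_prune(total, alive_idx, params)
    kept_ids = {total.loci[j].id for j in kept_idx}
    pruned = [loc.id for loc in cm.loci if loc.id not in kept_ids]
    cm = cm.subset_loci([j for j, loc in enumerate(cm.loci) if loc.id in kept_ids])
    report.add_stage("ld_prune", report.stages[-1][3], cm.n_loci, pruned, "ld")

    return CoreSelection(total=total, consensus=cm, core_indices=kept_idx,
                         report=report, params=params)
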
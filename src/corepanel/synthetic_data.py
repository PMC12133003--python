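"""Synthetic genotype fixtures emulating a multi-cultivar GBS study design.

The generator produces biallelic SNP genotypes for ``n_varieties`` discrete
cultivar populations diverged from a common ancestral pool under the
Balding–Nichols drift model: at each locus an ancestral allele frequency
``p`` is drawn, and each population's frequency is Beta-distributed with
mean ``p`` and variance ``Fst * p * (1 - p)`` (shape parameters
``p(1-F)/F`` and ``(1-p)(1-F)/F``).  Within a population genotypes are
drawn Binomial(2, freq), i.e. Hardy–Weinberg equilibrium holds within
cultivars.  Per-call sequencing depth is Poisson with the study's mean
coverage (11.6×), and a call is missing either completely at random
(``missing_rate``) or because its simulated depth is ≤ 4, so the depth
filter downstream has genuine work to do.

Defaults mirror the study design the analysis targets: 4 cultivars × 10
diploid seedlings, 31 chromosomes, mean depth 11.6×.

Two optional knobs exercise regimes the baseline model lacks:

* ``admixture_noise`` gives every sample a small off-cultivar ancestry
  fraction, so within-cultivar genotype identity drops below 100% and the
  70% consensus rule is non-trivial;
* ``dup_fraction`` block-copies a fraction of loci to an adjacent position
  with per-call flip probability ``dup_flip_prob``, creating the high-r²
  pairs LD pruning exists to remove.

Both default to off so the baseline fixture is exactly Balding–Nichols +
HWE, which the calibration tests rely on.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    Locus,
    VarietyAssignment,
    sort_loci,
    write_variety_map,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate",
    "emit_fixture",
    "weir_cockerham_fst",
]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the emulated study conditions: 4 cultivar populations of
    10 diploid individuals each, SNPs spread over 31 chromosomes, mean
    per-call depth 11.6×, Balding–Nichols differentiation Fst = 0.2 and
    5% completely-at-random missingness.
    """

    n_varieties: int = 4
    n_per_variety: int = 10
    n_loci: int = 40_000
    n_chrom: int = 31
    chrom_length: int = 17_000_000
    fst: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.05
    mean_depth: float = 11.6
    depth_missing_threshold: int = 4
    admixture_noise: float = 0.0
    dup_fraction: float = 0.0
    dup_flip_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_varieties, self.n_per_variety, self.n_chrom) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if not (0.0 < self.fst < 1.0):
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.admixture_noise < 1.0):
            raise ValueError("admixture_noise must be in [0, 1)")
        if not (0.0 <= self.dup_fraction < 1.0):
            raise ValueError("dup_fraction must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_varieties * self.n_per_variety


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth behind a simulated dataset, for recovery tests.

    ``ancestral_freq``: per-locus ancestral alt-allele frequency;
    ``pop_freq``: n_varieties × n_loci per-population alt frequencies;
    ``pop_labels``: cultivar label per sample;
    ``variety_names``: cultivar labels in population order.
    """

    ancestral_freq: np.ndarray
    pop_freq: np.ndarray
    pop_labels: list[str]
    variety_names: list[str]

    def __post_init__(self) -> None:
        self.ancestral_freq = np.asarray(self.ancestral_freq, dtype=float)
        self.pop_freq = np.asarray(self.pop_freq, dtype=float)
        for arr in (self.ancestral_freq, self.pop_freq):
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError("frequencies must lie in [0, 1]")
        if self.pop_freq.shape != (len(self.variety_names), self.ancestral_freq.size):
            raise ValueError("pop_freq shape inconsistent with config")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "ancestral_freq": self.ancestral_freq.round(6).tolist(),
            "pop_freq": self.pop_freq.round(6).tolist(),
            "pop_labels": self.pop_labels,
            "variety_names": self.variety_names,
        }
        path.write_text(json.dumps(payload))
        return path


def simulate_frequencies(cfg: SimulationConfig) -> SimulationTruth:
    """Draw ancestral and per-population allele frequencies.

    The ancestral minor-allele frequency is Uniform over ``cfg.maf_range``
    and assigned to the ref or the alt allele with equal probability; each
    population's alt frequency is then Balding–Nichols Beta around the
    ancestral value with drift parameter ``cfg.fst``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=cfg.n_loci)
    flip = rng.random(cfg.n_loci) < 0.5
    p = np.where(flip, 1.0 - maf, maf)  # ancestral alt-allele frequency

    f = cfg.fst
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    pop_freq = rng.beta(a, b, size=(cfg.n_varieties, cfg.n_loci)) if cfg.n_loci else (
        np.zeros((cfg.n_varieties, 0))
    )

    variety_names = [f"V{k + 1}" for k in range(cfg.n_varieties)]
    pop_labels = [
        variety_names[k] for k in range(cfg.n_varieties) for _ in range(cfg.n_per_variety)
    ]
    return SimulationTruth(
        ancestral_freq=p,
        pop_freq=pop_freq,
        pop_labels=pop_labels,
        variety_names=variety_names,
    )


def _place_loci(cfg: SimulationConfig, rng: np.random.Generator,
                n_loci: int) -> list[tuple[str, int]]:
    """Uniform placement of loci on chromosomes; returns sorted (chrom, pos)."""
    chrom_idx = rng.integers(0, cfg.n_chrom, size=n_loci)
    pos = rng.integers(1, cfg.chrom_length + 1, size=n_loci)
    width = len(str(cfg.n_chrom))
    names = [f"chr{i + 1:0{width}d}" for i in range(cfg.n_chrom)]
    placed = sorted((names[c], int(x)) for c, x in zip(chrom_idx, pos))
    # avoid coincident positions so locus ids stay unique
    out: list[tuple[str, int]] = []
    last: tuple[str, int] | None = None
    for chrom, p in placed:
        if last is not None and chrom == last[0] and p <= last[1]:
            p = last[1] + 1
        out.append((chrom, p))
        last = (chrom, p)
    return out


_ALLELE_PAIRS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


def simulate_genotypes(truth: SimulationTruth, cfg: SimulationConfig
                       ) -> tuple[GenotypeMatrix, VarietyAssignment]:
    """Draw genotypes, depths and missingness given the frequency truth.

    Genotypes are Binomial(2, sample frequency); the sample frequency is
    the population's unless ``admixture_noise`` mixes in the mean of the
    other populations.  Depth is Poisson(``mean_depth``); a call is missing
    if an MCAR draw falls below ``missing_rate`` or its depth is ≤ 4.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n, m = cfg.n_samples, cfg.n_loci
    pop_of_sample = np.repeat(np.arange(cfg.n_varieties), cfg.n_per_variety)

    freq = truth.pop_freq[pop_of_sample, :]  # n × m
    if cfg.admixture_noise > 0.0 and cfg.n_varieties > 1:
        others = (truth.pop_freq.sum(axis=0)[None, :] - truth.pop_freq[pop_of_sample, :])
        others /= cfg.n_varieties - 1
        freq = (1.0 - cfg.admixture_noise) * freq + cfg.admixture_noise * others

    geno = rng.binomial(2, freq).astype(np.int8)
    depth = rng.poisson(cfg.mean_depth, size=(n, m)).astype(np.int32)
    mcar = rng.random((n, m)) < cfg.missing_rate
    geno[mcar | (depth <= cfg.depth_missing_threshold)] = MISSING

    # optional LD blocks: adjacent near-copies of a subset of loci
    n_dup = int(round(cfg.dup_fraction * m))
    if n_dup > 0:
        dup_src = rng.choice(m, size=n_dup, replace=False)
        flips = rng.random((n, n_dup)) < cfg.dup_flip_prob
        dup_geno = geno[:, dup_src].copy()
        bump = rng.integers(0, 3, size=(n, n_dup)).astype(np.int8)
        ok = dup_geno != MISSING
        dup_geno[ok & flips] = bump[ok & flips]
        dup_depth = depth[:, dup_src].copy()
    else:
        dup_src = np.array([], dtype=int)
        dup_geno = np.zeros((n, 0), dtype=np.int8)
        dup_depth = np.zeros((n, 0), dtype=np.int32)

    placed = _place_loci(cfg, rng, m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    loci = [
        Locus(chrom=c, pos=p, ref=_ALLELE_PAIRS[k][0], alt=(_ALLELE_PAIRS[k][1],))
        for (c, p), k in zip(placed, pair_idx)
    ]

    if n_dup > 0:
        dup_loci = [
            Locus(chrom=loci[s].chrom, pos=loci[s].pos, ref=loci[s].ref,
                  alt=loci[s].alt, id=f"{loci[s].chrom}:{loci[s].pos}:dup")
            for s in dup_src
        ]
        loci = loci + dup_loci
        geno = np.concatenate([geno, dup_geno], axis=1)
        depth = np.concatenate([depth, dup_depth], axis=1)

    samples = [f"{lab}_s{i % cfg.n_per_variety + 1:02d}"
               for i, lab in enumerate(truth.pop_labels)]
    gm = sort_loci(GenotypeMatrix(samples=samples, loci=loci,
                                  genotypes=geno, depths=depth))
    assignment = VarietyAssignment(dict(zip(samples, truth.pop_labels)))
    return gm, assignment


def simulate(cfg: SimulationConfig
             ) -> tuple[GenotypeMatrix, VarietyAssignment, SimulationTruth]:
    """Convenience wrapper: frequencies then genotypes under one config."""
    truth = simulate_frequencies(cfg)
    gm, assignment = simulate_genotypes(truth, cfg)
    return gm, assignment, truth


def emit_fixture(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a cross-consistent VCF + cultivar TSV + truth JSON fixture."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, assignment, truth = simulate(cfg)
    paths = {
        "vcf": write_vcf(gm, outdir / "genotypes.vcf"),
        "varieties": write_variety_map(assignment, outdir / "varieties.tsv"),
        "truth": truth.to_json(outdir / "truth.json"),
    }
    return paths


def weir_cockerham_fst(gm: GenotypeMatrix, assignment: VarietyAssignment) -> float:
    """Multi-locus Weir–Cockerham theta (ratio of summed variance components).

    Calibration diagnostic for the simulator: under Balding–Nichols with a
    common drift parameter, theta estimates that parameter.  Uses the
    standard two-level (population / individual) a, b, c components for a
    biallelic locus and returns sum(a) / sum(a + b + c) over loci with at
    least two populations observed.
    """
    groups = assignment.group_indices(gm.samples)
    r = len(groups)
    if r < 2:
        raise ValueError("Fst needs at least two populations")
    G = gm.genotypes
    a_sum = b_sum = c_sum = 0.0
    idx_list = list(groups.values())
    for j in range(gm.n_loci):
        n_i, p_i, h_i = [], [], []
        for idx in idx_list:
            col = G[idx, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            n_i.append(col.size)
            p_i.append(col.sum() / (2.0 * col.size))
            h_i.append(np.mean(col == 1))
        if len(n_i) < 2:
            continue
        n_i = np.asarray(n_i, dtype=float)
        p_i = np.asarray(p_i)
        h_i = np.asarray(h_i)
        r_l = len(n_i)
        n_bar = n_i.mean()
        n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r_l - 1)
        p_bar = (n_i * p_i).sum() / n_i.sum()
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r_l - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / n_i.sum()
        if n_bar <= 1 or n_c == 0:
            continue
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r_l - 1) / r_l * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r_l - 1) / r_l * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    denom = a_sum + b_sum + c_sum
    if denom == 0:
        raise ValueError("no polymorphic information for Fst")
    return float(a_sum / denom)
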
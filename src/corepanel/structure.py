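"""Population-structure analyses: fingerprints, NJ tree, PCA, admixture.

Four views of the same genotype matrix:

* **Fingerprints** — one character per locus per sample (ref base for
  hom-ref, alt base for hom-alt, the IUPAC ambiguity code for a het, and
  ``-`` for missing), concatenated head to tail.
* **p-distance / neighbor-joining** — pairwise fraction of mismatching
  compared positions (missing positions excluded), a Saitou–Nei NJ tree,
  and bootstrap supports from resampling loci with replacement.
* **PCA** — eigendecomposition of the genomic relationship matrix built
  from standardized dosages ``(x − 2p)/sqrt(2p(1−p))`` with mean
  imputation of missing calls.
* **Admixture** — the K-ancestral-population binomial mixture: each
  individual carries ancestry fractions ``q_i`` (simplex) and population
  ``k`` carries allele frequencies ``f_k``; genotypes are
  Binomial(2, Σ_k q_ik f_kj).  Fitted by EM with random restarts; the
  number of populations is chosen by entry-masking cross-validation.

The admixture piece follows the statsmodels idiom: build an
:class:`AdmixtureModel` from data, call :meth:`~AdmixtureModel.fit`, get an
:class:`AdmixtureResults` carrying estimates and a :meth:`summary` table.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .core_selection import ConsensusMatrix
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "fingerprint_strings",
    "fingerprint_decode",
    "p_distance",
    "nj_tree",
    "bootstrap_support",
    "newick_with_support",
    "PcaResult",
    "pca",
    "AdmixtureModel",
    "AdmixtureResults",
    "admixture_em",
    "CvResult",
    "cv_choose_k",
]

# IUPAC ambiguity code for an unordered base pair
_IUPAC = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}


def _rows_and_labels(m: GenotypeMatrix | ConsensusMatrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, GenotypeMatrix):
        return m.genotypes, list(m.samples)
    return m.genotypes, list(m.varieties)


def fingerprint_strings(m: GenotypeMatrix | ConsensusMatrix) -> dict[str, str]:
    """Assemble per-sample genotype fingerprints, missing sites as ``-``.

    Alphabet per locus: hom-ref → the ref base; hom-alt → the (first) alt
    base; het → the IUPAC code of {ref, alt}; missing → ``-``.  All strings
    have length n_loci.
    """
    geno, labels = _rows_and_labels(m)
    chars = np.empty(geno.shape, dtype="U1")
    for j, loc in enumerate(m.loci):
        ref, alt = loc.ref, loc.alt[0]
        het = _IUPAC.get(frozenset((ref, alt)), "N") if ref != alt else "N"
        col = geno[:, j]
        chars[:, j] = "-"
        chars[col == 0, j] = ref
        chars[col == 1, j] = het
        chars[col == 2, j] = alt
    return {lab: "".join(row) for lab, row in zip(labels, chars)}


def fingerprint_decode(strings: Mapping[str, str],
                       loci: Sequence) -> np.ndarray:
    """Invert :func:`fingerprint_strings` back to genotype codes."""
    out = np.full((len(strings), len(loci)), MISSING, dtype=np.int8)
    for i, (_, s) in enumerate(strings.items()):
        if len(s) != len(loci):
            raise ValueError("fingerprint length does not match loci")
        for j, loc in enumerate(loci):
            ch = s[j]
            if ch == "-":
                continue
            if ch == loc.ref:
                out[i, j] = 0
            elif ch == loc.alt[0]:
                out[i, j] = 2
            elif ch == _IUPAC.get(frozenset((loc.ref, loc.alt[0]))):
                out[i, j] = 1
            else:
                raise ValueError(f"character {ch!r} outside the locus alphabet")
    return out


def p_distance(m: GenotypeMatrix | ConsensusMatrix | np.ndarray,
               labels: Sequence[str] | None = None
               ) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distance: mismatches / compared positions.

    Positions missing in either member of a pair are excluded; a pair with
    zero compared positions is an error.  Equals ``1 − similarity`` under
    the same comparison rule.
    """
    if isinstance(m, np.ndarray):
        geno = m
        labs = list(labels) if labels is not None else [str(i) for i in range(len(m))]
    else:
        geno, labs = _rows_and_labels(m)
    n = geno.shape[0]
    if n < 2:
        raise ValueError("p-distance needs at least two samples")
    V = (geno != MISSING)
    common = V.astype(np.int64) @ V.T.astype(np.int64)
    same = np.zeros_like(common)
    for c in (0, 1, 2):
        I = (geno == c).astype(np.int64)
        same += I @ I.T
    if np.any(common[np.triu_indices(n, k=1)] == 0):
        raise ValueError("a sample pair shares no compared positions")
    d = 1.0 - same / common
    np.fill_diagonal(d, 0.0)
    return d, labs


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch estimates clamped at 0.

    Returns a scikit-bio :class:`TreeNode` (rooted representation of the
    unrooted topology) serializable to Newick.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    dm = DistanceMatrix(dist, ids=list(labels))
    return nj(dm)


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller-side leaf set is not
    canonical on unrooted trees, both sides are keyed by the full leaf set)."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(leaf.name for leaf in node.tips())
        if 1 < len(clade) < len(all_leaves) - 1:
            # canonical side: the lexicographically smaller frozenset repr
            other = all_leaves - clade
            parts.add(min(clade, other, key=lambda s: sorted(s)))
    return parts


def bootstrap_support(m: GenotypeMatrix | ConsensusMatrix, b: int = 1000,
                      seed: int = 0) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Bootstrap the NJ tree by resampling loci with replacement.

    Returns the tree built from the full data, with each internal node
    annotated (``node.support``, fraction in [0, 1]) by how often its
    bipartition recurs among ``b`` replicate trees.  ``b = 0`` yields an
    un-annotated tree and an empty support map.
    """
    geno, labels = _rows_and_labels(m)
    n_loci = geno.shape[1]
    if n_loci < 1:
        raise ValueError("bootstrap needs at least one locus")
    d, labs = p_distance(geno, labels)
    tree = nj_tree(d, labs)
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    all_leaves = frozenset(labs)
    for _ in range(b):
        cols = rng.integers(0, n_loci, size=n_loci)
        try:
            db, _ = p_distance(geno[:, cols], labs)
        except ValueError:     # replicate with an empty comparison: skip
            continue
        for part in _bipartitions(nj_tree(db, labs)):
            counts[part] = counts.get(part, 0) + 1
    supports: dict[frozenset[str], float] = {}
    if b > 0:
        for node in tree.non_tips(include_self=False):
            clade = frozenset(leaf.name for leaf in node.tips())
            if not (1 < len(clade) < len(all_leaves) - 1):
                continue
            key = min(clade, all_leaves - clade, key=lambda s: sorted(s))
            sup = counts.get(key, 0) / b
            supports[key] = sup
            node.support = sup
    return tree, supports


def newick_with_support(tree: TreeNode) -> str:
    """Newick string with bootstrap supports as internal-node labels."""
    t = tree.copy()
    for node in t.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None:
            node.name = f"{sup:.3f}"
    buf = io.StringIO()
    t.write(buf, format="newick")
    return buf.getvalue().strip()


@dataclasses.dataclass
class PcaResult:
    """Sample coordinates and explained-variance fractions from the GRM."""

    samples: list[str]
    coordinates: np.ndarray        # n_samples × n_components
    variance_fraction: np.ndarray  # per component, of total positive mass
    eigenvalues: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample": self.samples, **cols})


def pca(gm: GenotypeMatrix | ConsensusMatrix, n_components: int | None = None
        ) -> PcaResult:
    """GRM-based principal components of standardized genotype dosages.

    Per polymorphic locus, dosage x is standardized to
    ``z = (x − 2p) / sqrt(2p(1−p))`` with missing calls imputed at the mean
    (z = 0); the GRM is ``Z Zᵀ / M``.  Coordinates are eigenvectors scaled
    by ``sqrt(eigenvalue)``; variance fractions are taken over the positive
    eigenvalue mass.
    """
    geno, labels = _rows_and_labels(gm)
    n = geno.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    ok = geno != MISSING
    n_obs = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, geno, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    poly = (n_obs > 0) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all loci are monomorphic; PCA undefined")
    p = p[poly]
    X = geno[:, poly].astype(float)
    V = ok[:, poly]
    Z = (np.where(V, X, 2.0 * p) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = Z.shape[1]
    grm = Z @ Z.T / m
    evals, evecs = np.linalg.eigh(grm)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0.0) * 1e-12
    total = evals[pos].sum()
    k = n_components or int(pos.sum())
    k = min(k, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    return PcaResult(
        samples=labels,
        coordinates=coords,
        variance_fraction=evals[:k] / total,
        eigenvalues=evals,
    )


class AdmixtureModel:
    """Binomial admixture model of genotype dosages for K ancestral pools.

    Parameters
    ----------
    gm : GenotypeMatrix
        Sample-level genotypes; missing calls are excluded from the
        likelihood.
    k : int
        Number of ancestral populations (1 ≤ k ≤ n_samples).
    """

    _EPS = 1e-6

    def __init__(self, gm: GenotypeMatrix | np.ndarray, k: int,
                 samples: Sequence[str] | None = None):
        if isinstance(gm, GenotypeMatrix):
            geno = gm.genotypes
            samples = list(gm.samples)
        else:
            geno = np.asarray(gm)
            samples = list(samples) if samples is not None else [
                str(i) for i in range(geno.shape[0])
            ]
        n, m_loci = geno.shape
        if m_loci < 1:
            raise ValueError("admixture needs at least one locus")
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, n_samples], got {k} for n={n}")
        self.k = int(k)
        self.samples = samples
        self.W = (geno != MISSING)
        self.G = np.where(self.W, geno, 0).astype(float)
        self.n, self.m = n, m_loci

    def loglike(self, q: np.ndarray, f: np.ndarray) -> float:
        """Binomial log-likelihood (binomial coefficients omitted)."""
        P = np.clip(q @ f, self._EPS, 1.0 - self._EPS)
        ll = self.W * (self.G * np.log(P) + (2.0 - self.G) * np.log1p(-P))
        return float(ll.sum())

    def _em_step(self, q: np.ndarray, f: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        P = np.clip(q @ f, self._EPS, 1.0 - self._EPS)
        A = self.W * self.G / P                  # expected alt-allele weight
        B = self.W * (2.0 - self.G) / (1.0 - P)  # expected ref-allele weight
        q_new = q * (A @ f.T + B @ (1.0 - f).T)
        q_new /= q_new.sum(axis=1, keepdims=True)
        alt = f * (q.T @ A)
        ref = (1.0 - f) * (q.T @ B)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_new = alt / (alt + ref)
        f_new[~np.isfinite(f_new)] = 0.5
        return q_new, np.clip(f_new, self._EPS, 1.0 - self._EPS)

    def _init(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        q = rng.dirichlet(np.ones(self.k), size=self.n)
        base = self.G.sum(axis=0) / np.maximum(2.0 * self.W.sum(axis=0), 1.0)
        f = np.clip(base[None, :] + rng.normal(0.0, 0.1, size=(self.k, self.m)),
                    self._EPS, 1.0 - self._EPS)
        return q, f

    def fit(self, seed: int = 0, n_restarts: int = 8, max_iter: int = 2000,
            tol: float = 1e-6) -> "AdmixtureResults":
        """EM with random restarts; the best-likelihood solution is kept.

        ``tol`` is the relative log-likelihood change that stops a run; the
        log-likelihood is non-decreasing along every EM path.
        """
        best: AdmixtureResults | None = None
        for r in range(max(1, n_restarts)):
            rng = np.random.default_rng(np.random.SeedSequence([seed, self.k, r]))
            q, f = self._init(rng)
            path = [self.loglike(q, f)]
            converged = False
            for _ in range(max_iter):
                q, f = self._em_step(q, f)
                ll = self.loglike(q, f)
                path.append(ll)
                if abs(ll - path[-2]) <= tol * (abs(path[-2]) + 1.0):
                    converged = True
                    break
            res = AdmixtureResults(
                model=self, k=self.k, Q=q, F=f, loglik=path[-1],
                loglik_path=np.asarray(path), n_iter=len(path) - 1,
                converged=converged, restart=r,
            )
            if best is None or res.loglik > best.loglik:
                best = res
        assert best is not None
        return best


@dataclasses.dataclass
class AdmixtureResults:
    """Fitted ancestry fractions Q, population frequencies F and diagnostics."""

    model: AdmixtureModel
    k: int
    Q: np.ndarray            # n_samples × k, rows on the simplex
    F: np.ndarray            # k × n_loci allele frequencies
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    restart: int

    def predicted_dosage(self) -> np.ndarray:
        """Expected genotype dosage 2·QF under the fitted model."""
        return 2.0 * (self.Q @ self.F)

    def hard_labels(self) -> np.ndarray:
        """Max-ancestry component per sample."""
        return self.Q.argmax(axis=1)

    def q_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"K{i + 1}" for i in range(self.k)])
        df.insert(0, "sample", self.model.samples)
        return df

    def summary(self) -> str:
        lines = [
            "Admixture model (binomial EM)",
            f"  K components:      {self.k}",
            f"  samples x loci:    {self.model.n} x {self.model.m}",
            f"  log-likelihood:    {self.loglik:.3f}",
            f"  EM iterations:     {self.n_iter} (restart {self.restart}, "
            f"{'converged' if self.converged else 'max_iter reached'})",
            f"  mean max ancestry: {self.Q.max(axis=1).mean():.3f}",
            "",
            self.q_frame().round(3).to_string(index=False),
        ]
        return "\n".join(lines)


def admixture_em(gm: GenotypeMatrix | np.ndarray, k: int, seed: int = 0,
                 max_iter: int = 2000, tol: float = 1e-6,
                 n_restarts: int = 8) -> AdmixtureResults:
    """Functional wrapper over :class:`AdmixtureModel`."""
    return AdmixtureModel(gm, k).fit(seed=seed, n_restarts=n_restarts,
                                     max_iter=max_iter, tol=tol)


@dataclasses.dataclass
class CvResult:
    """Cross-validation errors per K and the selected K*."""

    errors: dict[int, float]          # mean RMSE per K
    fold_errors: dict[int, list[float]]
    best_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": list(self.errors), "cv_error": list(self.errors.values())}
        )


def cv_choose_k(gm: GenotypeMatrix | np.ndarray, k_range: Sequence[int],
                folds: int = 5, seed: int = 0, n_restarts: int = 8,
                max_iter: int = 2000, tol: float = 1e-6) -> CvResult:
    """Choose K by entry-masking cross-validation of the admixture model.

    Non-missing genotype entries are partitioned into ``folds`` random
    groups; per fold the group is masked, the model refitted, and the
    held-out entries scored by the RMSE of ``g − 2·QF``.  The CV error per
    K is the mean over folds; K* is the argmin (ties → smaller K).
    """
    if not len(k_range):
        raise ValueError("k_range must be non-empty")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    geno = gm.genotypes if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    obs = np.argwhere(geno != MISSING)
    if len(obs) < folds:
        raise ValueError("too few non-missing entries for the requested folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    perm = rng.permutation(len(obs))
    assignments = np.arange(len(obs)) % folds
    fold_of_entry = np.empty(len(obs), dtype=int)
    fold_of_entry[perm] = assignments

    fold_errors: dict[int, list[float]] = {int(k): [] for k in k_range}
    for fold in range(folds):
        mask = obs[fold_of_entry == fold]
        train = geno.copy()
        train[mask[:, 0], mask[:, 1]] = MISSING
        truth = geno[mask[:, 0], mask[:, 1]].astype(float)
        for k in k_range:
            fit = AdmixtureModel(train, int(k)).fit(
                seed=seed * 1000 + fold, n_restarts=n_restarts,
                max_iter=max_iter, tol=tol,
            )
            pred = fit.predicted_dosage()[mask[:, 0], mask[:, 1]]
            rmse = float(np.sqrt(np.mean((truth - pred) ** 2)))
            fold_errors[int(k)].append(rmse)
    errors = {k: float(np.mean(v)) for k, v in fold_errors.items()}
    best_k = min(sorted(errors), key=lambda k: (errors[k], k))
    return CvResult(errors=errors, fold_errors=fold_errors, best_k=best_k)
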
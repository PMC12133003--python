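"""Independent brute-force oracles used by the property tests.

These deliberately share no code with the package: exact rational
enumeration for the Hardy–Weinberg test, per-pair corrcoef for LD windows,
and random additive trees (with path-metric distances) for neighbor
joining.
"""

from fractions import Fraction
from math import comb, factorial

import numpy as np

from corepanel.genotype_io import MISSING


def hwe_enumeration_oracle(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact HWE test p-value by full enumeration in rational arithmetic."""
    n = n_homref + n_het + n_homalt
    if n == 0:
        return 1.0
    n_a = 2 * n_homref + n_het
    n_b = 2 * n_homalt + n_het
    rare, common = min(n_a, n_b), max(n_a, n_b)

    def prob(het: int) -> Fraction:
        homr = (rare - het) // 2
        homc = (common - het) // 2
        num = Fraction(factorial(n) * 2 ** het * factorial(rare) * factorial(common))
        den = Fraction(
            factorial(homr) * factorial(het) * factorial(homc) * factorial(2 * n)
        )
        return num * den ** -1

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def pairwise_complete_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over samples non-missing in both columns."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0.0 or yv.std() == 0.0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


class AdditiveTree:
    """A random binary tree with positive branch lengths and its path metric."""

    def __init__(self, n_leaves: int, rng: np.random.Generator):
        # nodes: leaf ids 0..n-1; join random pairs under fresh internal nodes
        parent: dict[int, tuple[int, float]] = {}
        active = list(range(n_leaves))
        next_id = n_leaves
        while len(active) > 2:
            i, j = rng.choice(len(active), size=2, replace=False)
            a, b = active[min(i, j)], active[max(i, j)]
            parent[a] = (next_id, float(rng.uniform(0.5, 2.0)))
            parent[b] = (next_id, float(rng.uniform(0.5, 2.0)))
            active = [x for x in active if x not in (a, b)] + [next_id]
            next_id += 1
        # connect the last two with a single (root) edge
        a, b = active
        parent[a] = (next_id, float(rng.uniform(0.5, 2.0)))
        parent[b] = (next_id, float(rng.uniform(0.5, 2.0)))
        self.parent = parent
        self.n_leaves = n_leaves
        self.root = next_id

    def _path_to_root(self, node: int) -> dict[int, float]:
        dist, total = {}, 0.0
        while node in self.parent:
            up, length = self.parent[node]
            total += length
            dist[up] = total
            node = up
        return dist

    def distance_matrix(self) -> np.ndarray:
        n = self.n_leaves
        d = np.zeros((n, n))
        paths = [self._path_to_root(i) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                shared = set(paths[i]) & set(paths[j])
                mrca = min(shared, key=lambda a: paths[i][a] + paths[j][a])
                d[i, j] = d[j, i] = paths[i][mrca] + paths[j][mrca]
        return d
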
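import numpy as np
import pytest

from corepanel import (
    FilterParams,
    SimulationConfig,
    select_core,
    simulate,
)

TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##contig=<ID=chr1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT:DP\t0/0:3\t0/1:9
chr1\t200\t.\tG\tT\t.\tPASS\t.\tGT:DP\t1/1:7\t./.:0
chr1\t300\trs3\tT\tA\t.\tPASS\t.\tGT\t0/1\t1|0
"""


@pytest.fixture(scope="session")
def toy_vcf_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("io") / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture(scope="session")
def small_sim():
    """3k-locus 4-population fixture under the default study conditions."""
    cfg = SimulationConfig(n_loci=3000, seed=1)
    gm, assignment, truth = simulate(cfg)
    return gm, assignment, truth


@pytest.fixture(scope="session")
def small_sel(small_sim):
    gm, assignment, _ = small_sim
    return select_core(gm, assignment, FilterParams())


@pytest.fixture(scope="session")
def default_sim():
    """The full default fixture (40k loci, seed 1) used by the headline checks."""
    cfg = SimulationConfig(seed=1)
    gm, assignment, truth = simulate(cfg)
    return gm, assignment, truth


@pytest.fixture(scope="session")
def default_sel(default_sim):
    gm, assignment, _ = default_sim
    return select_core(gm, assignment, FilterParams())


@pytest.fixture(scope="session")
def clean_sim():
    """No missingness, saturating depth: every call observed."""
    cfg = SimulationConfig(n_loci=1200, seed=5, missing_rate=0.0, mean_depth=1000.0)
    return simulate(cfg)


def best_permutation_agreement(labels_a, labels_b) -> float:
    """Max over label permutations of the agreement between two clusterings."""
    from itertools import permutations

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    cats_a = sorted(set(a.tolist()))
    cats_b = sorted(set(b.tolist()))
    best = 0.0
    for perm in permutations(cats_b):
        if len(perm) < len(cats_a):
            continue
        mapping = dict(zip(cats_a, perm))
        best = max(best, float(np.mean([mapping[x] == y for x, y in zip(a, b)])))
    return best
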
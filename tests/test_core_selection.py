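import numpy as np
import pytest
from _oracles import hwe_enumeration_oracle, pairwise_complete_r2

from corepanel.core_selection import (
    ConsensusMatrix,
    FilterParams,
    FilterReport,
    consensus_genotypes,
    consensus_maf,
    filter_depth_biallelic,
    hwe_exact_test,
    ld_prune,
    missing_maf_filter,
    pic_filter,
    polymorphism_hwe_filter,
    select_core,
)
from corepanel.genotype_io import MISSING, GenotypeMatrix, Locus, VarietyAssignment
from corepanel.synthetic_data import SimulationConfig, simulate


def _matrix(codes, depths=None, loci=None, samples=None):
    codes = np.array(codes, dtype=np.int8)
    n, m = codes.shape
    if loci is None:
        loci = [Locus("chr1", 10 * (j + 1), "A", ("C",)) for j in range(m)]
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        loci=loci,
        genotypes=codes,
        depths=np.array(depths, dtype=np.int32) if depths is not None
        else np.full((n, m), 30, dtype=np.int32),
    )


class TestDepthBiallelic:
    def test_depth_four_is_masked_five_is_kept(self):
        gm = _matrix([[1, 1]], depths=[[4, 5]])
        out, removed = filter_depth_biallelic(gm, FilterParams())
        assert out.genotypes[0, 0] == MISSING
        assert out.genotypes[0, 1] == 1
        assert removed == []

    def test_uniform_depth_five_unchanged(self):
        gm = _matrix([[0, 1], [2, 1]], depths=[[5, 5], [5, 5]])
        out, _ = filter_depth_biallelic(gm, FilterParams())
        np.testing.assert_array_equal(out.genotypes, gm.genotypes)

    def test_triallelic_locus_dropped_and_reported(self):
        loci = [Locus("chr1", 10, "A", ("C",)), Locus("chr1", 20, "A", ("C", "T"))]
        gm = _matrix([[0, 0]], loci=loci)
        out, removed = filter_depth_biallelic(gm, FilterParams())
        assert [l.id for l in out.loci] == ["chr1:10"]
        assert removed == ["chr1:20"]


class TestConsensus:
    def _assignment(self, n=10):
        return VarietyAssignment({f"s{i}": "cv" for i in range(n)})

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 0, 0), 0),        # unanimous
            ((7, 3, 0), 0),         # 70% exactly: boundary inclusive
            ((6, 4, 0), MISSING),   # 60% below threshold
            ((0, 0, 10), 2),
        ],
    )
    def test_identity_rule_boundaries(self, counts, expected):
        col = sum(([c] * k for c, k in zip((0, 1, 2), counts)), [])
        gm = _matrix(np.array(col).reshape(-1, 1))
        cm = consensus_genotypes(gm, self._assignment(), FilterParams())
        assert cm.genotypes[0, 0] == expected

    def test_missing_calls_shrink_the_denominator(self):
        # 5 of 7 observed calls agree (71%) with 3 missing
        col = [0, 0, 0, 0, 0, 1, 1, MISSING, MISSING, MISSING]
        gm = _matrix(np.array(col).reshape(-1, 1))
        cm = consensus_genotypes(gm, self._assignment(), FilterParams())
        assert cm.genotypes[0, 0] == 0

    def test_all_missing_gives_missing(self):
        gm = _matrix(np.full((10, 1), MISSING))
        cm = consensus_genotypes(gm, self._assignment(), FilterParams())
        assert cm.genotypes[0, 0] == MISSING

    def test_invariant_to_sample_order_and_labels(self, small_sim):
        gm, assignment, _ = small_sim
        sub = gm.subset_loci(range(300))
        cm = consensus_genotypes(sub, assignment, FilterParams())
        perm = np.random.default_rng(0).permutation(sub.n_samples)
        shuffled = sub.subset_samples(perm)
        relabel = VarietyAssignment(
            {s: "grp_" + assignment.mapping[s] for s in shuffled.samples}
        )
        cm2 = consensus_genotypes(shuffled, relabel, FilterParams())
        order = [cm2.varieties.index("grp_" + v) for v in cm.varieties]
        np.testing.assert_array_equal(cm.genotypes, cm2.genotypes[order, :])


class TestHweExactTest:
    def test_equals_enumeration_oracle_for_all_small_tables(self):
        for n in range(1, 26):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    c = n - a - b
                    assert hwe_exact_test(a, b, c) == pytest.approx(
                        hwe_enumeration_oracle(a, b, c), abs=1e-12
                    )

    def test_monomorphic_is_uninformative(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_all_homozygote_extreme_is_significant(self):
        p = hwe_exact_test(5, 0, 5)
        assert p == pytest.approx(hwe_enumeration_oracle(5, 0, 5), abs=1e-12)
        assert p < 0.01

    def test_empty_table_returns_one_by_convention(self):
        assert hwe_exact_test(0, 0, 0) == 1.0


class TestPolymorphismHwe:
    def _cm(self, rows):
        rows = np.array(rows, dtype=np.int8)
        loci = [Locus("chr1", 10 * (j + 1), "A", ("C",)) for j in range(rows.shape[1])]
        return ConsensusMatrix(
            varieties=[f"v{i}" for i in range(rows.shape[0])], loci=loci,
            genotypes=rows,
        )

    def test_uniform_consensus_removed(self):
        cm = self._cm([[0], [0], [0], [0]])
        gm = _matrix(np.zeros((4, 1)))
        out, reasons = polymorphism_hwe_filter(cm, gm, FilterParams())
        assert out.n_loci == 0 and reasons["chr1:10"] == "non_polymorphic"

    def test_identical_nonmissing_with_gap_removed(self):
        cm = self._cm([[0], [0], [0], [MISSING]])
        gm = _matrix(np.zeros((4, 1)))
        out, reasons = polymorphism_hwe_filter(cm, gm, FilterParams())
        assert out.n_loci == 0 and reasons["chr1:10"] == "non_polymorphic"

    def test_extreme_heterozygote_deficit_removed_by_hwe(self):
        # 20 hom-ref, 0 het, 20 hom-alt pooled: exact p far below 1e-5
        col = np.array([0] * 20 + [2] * 20, dtype=np.int8).reshape(-1, 1)
        gm = _matrix(col)
        cm = self._cm([[0], [0], [2], [2]])
        assert hwe_enumeration_oracle(20, 0, 20) < 1e-5
        out, reasons = polymorphism_hwe_filter(cm, gm, FilterParams())
        assert out.n_loci == 0 and reasons["chr1:10"] == "hwe"

    def test_polymorphic_in_equilibrium_kept(self):
        col = np.array([0] * 10 + [1] * 20 + [2] * 10, dtype=np.int8).reshape(-1, 1)
        gm = _matrix(col)
        cm = self._cm([[0], [1], [1], [2]])
        out, _ = polymorphism_hwe_filter(cm, gm, FilterParams())
        assert out.n_loci == 1


class TestMissingMafPic:
    def _cm(self, rows):
        rows = np.array(rows, dtype=np.int8)
        loci = [Locus("chr1", 10 * (j + 1), "A", ("C",)) for j in range(rows.shape[1])]
        return ConsensusMatrix(
            varieties=[f"v{i}" for i in range(rows.shape[0])], loci=loci,
            genotypes=rows,
        )

    def test_missingness_boundary_at_four_cultivars(self):
        # 1/4 = 25% kept, 2/4 = 50% removed
        cm = self._cm([[0, 0], [0, 0], [2, MISSING], [MISSING, MISSING]])
        out, reasons = missing_maf_filter(cm, FilterParams())
        assert [l.id for l in out.loci] == ["chr1:10"]
        assert reasons["chr1:20"] == "missingness"

    def test_minimum_nonzero_consensus_maf_kept(self):
        # (0,0,0,1): one alt allele of eight -> MAF 0.125 >= 0.01
        cm = self._cm([[0], [0], [0], [1]])
        assert consensus_maf(cm)[0] == pytest.approx(0.125)
        out, _ = missing_maf_filter(cm, FilterParams())
        assert out.n_loci == 1

    def test_zero_maf_removed(self):
        cm = self._cm([[0], [0], [0], [0]])
        out, reasons = missing_maf_filter(cm, FilterParams())
        assert out.n_loci == 0 and reasons["chr1:10"] == "maf"

    def test_pic_filter_boundaries(self):
        # maf 0.125 -> PIC 0.195 kept; monomorphic -> PIC 0 removed
        cm = self._cm([[0, 0], [0, 0], [0, 0], [1, 0]])
        out, reasons = pic_filter(cm, FilterParams())
        assert [l.id for l in out.loci] == ["chr1:10"]
        assert reasons["chr1:20"] == "pic"

    def test_custom_min_pic_of_one_removes_everything(self):
        cm = self._cm([[0], [1], [2], [1]])
        out, reasons = pic_filter(cm, FilterParams(min_pic=1.0))
        assert out.n_loci == 0


class TestLdPrune:
    def test_identical_columns_one_removed(self):
        col = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=np.int8)
        gm = _matrix(np.stack([col, col], axis=1))
        kept = ld_prune(gm, None, FilterParams())
        assert len(kept) == 1

    def test_independent_columns_all_kept(self, small_sim):
        gm, _, _ = small_sim
        sub = gm.subset_loci(range(120))
        kept = ld_prune(sub, None, FilterParams())
        assert len(kept) == 120

    def test_survivors_match_brute_force_window_oracle(self):
        cfg = SimulationConfig(n_loci=150, seed=21, dup_fraction=0.25,
                               missing_rate=0.02, mean_depth=30.0, n_chrom=2)
        gm, _, _ = simulate(cfg)
        params = FilterParams()
        kept = set(ld_prune(gm, None, params))
        removed = set(range(gm.n_loci)) - kept
        assert removed  # the duplicated blocks force removals
        chroms = np.array([l.chrom for l in gm.loci])
        for chrom in np.unique(chroms):
            idx = np.flatnonzero(chroms == chrom)
            start = 0
            while True:
                win = idx[start:start + params.ld_window]
                for ai in range(len(win)):
                    for bi in range(ai + 1, len(win)):
                        a, b = win[ai], win[bi]
                        r2 = pairwise_complete_r2(
                            gm.genotypes[:, a], gm.genotypes[:, b]
                        )
                        if a in kept and b in kept:
                            assert r2 <= params.ld_r2 + 1e-12
                if start + params.ld_window >= len(idx):
                    break
                start += params.ld_step
        # every removed locus had a high-r2 partner in a shared window
        for a in removed:
            chrom_idx = np.flatnonzero(chroms == chroms[a])
            pos = np.flatnonzero(chrom_idx == a)[0]
            neighbors = chrom_idx[max(0, pos - params.ld_window + 1):
                                  pos + params.ld_window]
            assert any(
                pairwise_complete_r2(gm.genotypes[:, a], gm.genotypes[:, b])
                > params.ld_r2
                for b in neighbors if b != a
            )


class TestSelectCore:
    def test_report_arithmetic_and_monotonicity(self, small_sel):
        frame = small_sel.report.to_frame()
        assert (frame["loci_in"] - frame["loci_removed"] == frame["loci_out"]).all()
        assert (frame["loci_out"].diff().dropna() <= 0).all()
        assert list(frame["loci_in"][1:]) == list(frame["loci_out"][:-1])

    def test_surviving_loci_satisfy_all_thresholds(self, small_sel):
        params = small_sel.params
        cm = small_sel.consensus
        assert cm.n_loci > 0
        maf = consensus_maf(cm)
        miss = (cm.genotypes == MISSING).mean(axis=0)
        p = maf
        pic = 1 - (p ** 2 + (1 - p) ** 2) - 2 * p ** 2 * (1 - p) ** 2
        assert np.all(maf >= params.min_maf)
        assert np.all(miss <= params.max_missing)
        assert np.all(pic >= params.min_pic)

    def test_impossible_pic_threshold_empties_panel(self, small_sim):
        gm, assignment, _ = small_sim
        sub = gm.subset_loci(range(400))
        sel = select_core(sub, assignment, FilterParams(min_pic=1.0))
        assert sel.core_indices == []
        stage = dict((s[0], s) for s in sel.report.stages)["pic"]
        assert stage[3] == 0 and stage[2] == stage[1]

    def test_monomorphic_input_empties_at_polymorphism_stage(self):
        gm = _matrix(np.zeros((40, 5)))
        assignment = VarietyAssignment(
            {f"s{i}": f"v{i % 4}" for i in range(40)}
        )
        sel = select_core(gm, assignment, FilterParams())
        assert sel.core_indices == []
        stage = dict((s[0], s) for s in sel.report.stages)["polymorphism_hwe"]
        assert stage[2] == 5


class TestFilterReport:
    def test_stage_chaining_enforced(self):
        report = FilterReport()
        report.add_stage("a", 10, 8)
        with pytest.raises(ValueError):
            report.add_stage("b", 9, 9)

    def test_negative_removal_rejected(self):
        report = FilterReport()
        with pytest.raises(ValueError):
            report.add_stage("a", 5, 6)
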
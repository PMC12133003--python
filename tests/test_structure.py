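import numpy as np
import pytest
from _oracles import AdditiveTree

from conftest import best_permutation_agreement
from corepanel.genotype_io import MISSING, GenotypeMatrix, Locus
from corepanel.similarity import pairwise_similarity
from corepanel.structure import (
    AdmixtureModel,
    admixture_em,
    bootstrap_support,
    cv_choose_k,
    fingerprint_decode,
    fingerprint_strings,
    newick_with_support,
    nj_tree,
    p_distance,
    pca,
)
from corepanel.synthetic_data import SimulationConfig, simulate


def _gm(codes, refs=None, alts=None):
    codes = np.array(codes, dtype=np.int8)
    n, m = codes.shape
    refs = refs or ["A"] * m
    alts = alts or ["C"] * m
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        loci=[Locus("chr1", 10 * (j + 1), refs[j], (alts[j],)) for j in range(m)],
        genotypes=codes,
        depths=np.full((n, m), 30, dtype=np.int32),
    )


class TestFingerprints:
    def test_zero_locus_matrix_gives_empty_strings(self):
        gm = _gm(np.zeros((2, 0)))
        assert fingerprint_strings(gm) == {"s0": "", "s1": ""}

    def test_alphabet_and_missing_dash(self):
        gm = _gm([[0, 1, MISSING]], refs=["A", "A", "G"], alts=["C", "C", "T"])
        assert fingerprint_strings(gm)["s0"] == "AM-"

    def test_round_trip_to_codes(self, small_sim):
        gm, _, _ = small_sim
        sub = gm.subset_loci(range(150))
        strings = fingerprint_strings(sub)
        decoded = fingerprint_decode(strings, sub.loci)
        np.testing.assert_array_equal(decoded, sub.genotypes)


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        gm = _gm([[0, 1, 2], [0, 1, 2]])
        d, _ = p_distance(gm)
        assert d[0, 1] == 0.0

    def test_hand_counted_distance(self):
        # strings "AC-" vs "AG-": one mismatch over two compared positions
        gm = _gm([[0, 0, MISSING], [0, 2, MISSING]])
        d, _ = p_distance(gm)
        assert d[0, 1] == pytest.approx(0.5)

    def test_complement_of_similarity(self, small_sim):
        gm, _, _ = small_sim
        sub = gm.subset_loci(range(400))
        d, _ = p_distance(sub)
        sim = pairwise_similarity(sub)
        np.testing.assert_allclose(d, 1.0 - sim.values, atol=1e-12)

    def test_no_shared_positions_rejected(self):
        gm = _gm([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError):
            p_distance(gm)


class TestNeighborJoining:
    @pytest.mark.parametrize("n_leaves", [5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        tree = AdditiveTree(n_leaves, rng)
        d = tree.distance_matrix()
        labels = [f"t{i}" for i in range(n_leaves)]
        nj = nj_tree(d, labels)
        # an additive metric determines its tree uniquely: recovering all
        # leaf-to-leaf path lengths proves topology and branch lengths
        tt = nj.tip_tip_distances(labels)
        recovered = np.asarray(tt.data)
        np.testing.assert_allclose(recovered, d, atol=1e-9)

    def test_three_taxa_forced_topology(self):
        d = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 3.0], [3.0, 3.0, 0.0]])
        tree = nj_tree(d, ["a", "b", "c"])
        tt = tree.tip_tip_distances(["a", "b", "c"])
        np.testing.assert_allclose(np.asarray(tt.data), d, atol=1e-9)

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_cultivars_form_monophyletic_clades(self, small_sim):
        gm, assignment, _ = small_sim
        sub = gm.subset_loci(range(1500))
        d, labels = p_distance(sub)
        tree = nj_tree(d, labels)
        tips = set(labels)
        clades = {frozenset(l.name for l in n.tips())
                  for n in tree.non_tips(include_self=False)}
        for variety, members in assignment.groups().items():
            group = frozenset(members)
            assert group in clades or (tips - group) in clades


class TestBootstrap:
    def test_zero_replicates_give_no_supports(self, small_sim):
        gm, _, _ = small_sim
        _, supports = bootstrap_support(gm.subset_loci(range(50)), b=0, seed=1)
        assert supports == {}

    def test_fixed_seed_reproducible(self, small_sim):
        gm, _, _ = small_sim
        sub = gm.subset_loci(range(120))
        _, s1 = bootstrap_support(sub, b=30, seed=9)
        _, s2 = bootstrap_support(sub, b=30, seed=9)
        assert s1 == s2

    def test_well_separated_cultivar_clades_are_supported(self, small_sim):
        gm, assignment, _ = small_sim
        sub = gm.subset_loci(range(1500))
        tree, supports = bootstrap_support(sub, b=100, seed=2)
        tips = frozenset(s for s in sub.samples)
        for variety, members in assignment.groups().items():
            group = frozenset(members)
            key = min(group, tips - group, key=lambda s: sorted(s))
            assert supports.get(key, 0.0) >= 0.95

    def test_newick_carries_support_labels(self, small_sim):
        gm, _, _ = small_sim
        tree, supports = bootstrap_support(gm.subset_loci(range(200)), b=20, seed=3)
        text = newick_with_support(tree)
        assert text.endswith(";") and "0." in text


class TestPca:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(6)
        row = rng.integers(0, 3, size=80)
        codes = np.stack([row, row, 2 - row])
        res = pca(_gm(codes))
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1],
                                   atol=1e-9)

    def test_grm_reconstructed_from_coordinates(self, small_sim):
        gm, _, _ = small_sim
        sub = gm.subset_loci(range(500))
        res = pca(sub)
        grm = res.coordinates @ res.coordinates.T
        assert np.allclose(grm, grm.T)
        assert res.variance_fraction[0] >= res.variance_fraction[-1]
        assert res.variance_fraction.sum() <= 1.0 + 1e-9

    def test_monomorphic_input_rejected(self):
        with pytest.raises(ValueError):
            pca(_gm(np.zeros((4, 10))))

    def test_four_populations_separate_into_clusters(self, small_sim):
        from sklearn.metrics import silhouette_score

        gm, assignment, _ = small_sim
        sub = gm.subset_loci(range(2000))
        res = pca(sub)
        labels = [assignment.mapping[s] for s in sub.samples]
        score = silhouette_score(res.coordinates[:, :3], labels)
        assert score > 0.8


class TestAdmixture:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(12, 60)).astype(np.int8)
        gm = _gm(codes)
        fit = admixture_em(gm, 1, seed=0, n_restarts=1, max_iter=50)
        np.testing.assert_allclose(fit.Q, 1.0)
        np.testing.assert_allclose(
            fit.F[0], codes.mean(axis=0) / 2.0, atol=1e-5
        )
        model = AdmixtureModel(gm, 1)
        assert fit.loglik == pytest.approx(model.loglike(fit.Q, fit.F), abs=1e-6)

    def test_loglikelihood_monotone_along_em_path(self, small_sim):
        gm, _, _ = small_sim
        sub = gm.subset_loci(range(300))
        fit = admixture_em(sub, 3, seed=1, n_restarts=2, max_iter=150)
        diffs = np.diff(fit.loglik_path)
        assert np.all(diffs >= -1e-9)

    def test_q_rows_stay_on_simplex(self, small_sim):
        gm, _, _ = small_sim
        fit = admixture_em(gm.subset_loci(range(300)), 4, seed=2, n_restarts=1,
                           max_iter=100)
        assert np.all(fit.Q >= 0)
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_four_population_recovery(self, small_sim):
        gm, assignment, _ = small_sim
        sub = gm.subset_loci(range(2000))
        fit = admixture_em(sub, 4, seed=3, n_restarts=4)
        assert fit.Q.max(axis=1).mean() >= 0.9
        truth = [assignment.mapping[s] for s in sub.samples]
        agreement = best_permutation_agreement(truth, fit.hard_labels().tolist())
        assert agreement >= 0.95

    def test_degenerate_k_rejected(self, small_sim):
        gm, _, _ = small_sim
        with pytest.raises(ValueError):
            AdmixtureModel(gm, gm.n_samples + 1)

    def test_summary_mentions_fit_dimensions(self, small_sim):
        gm, _, _ = small_sim
        fit = admixture_em(gm.subset_loci(range(100)), 2, seed=0, n_restarts=1,
                           max_iter=60)
        text = fit.summary()
        assert "K components:      2" in text
        assert "log-likelihood" in text


class TestCvChooseK:
    def test_single_population_selects_k1(self):
        cfg = SimulationConfig(n_varieties=1, n_per_variety=24, n_loci=600,
                               seed=31, missing_rate=0.0, mean_depth=1000.0)
        gm, _, _ = simulate(cfg)
        cv = cv_choose_k(gm, [1, 2, 3], folds=3, seed=1, n_restarts=2,
                         max_iter=300)
        assert cv.best_k == 1

    def test_fixed_seed_reproducible_curve(self, small_sim):
        gm, _, _ = small_sim
        sub = gm.subset_loci(range(250))
        cv1 = cv_choose_k(sub, [1, 2], folds=2, seed=7, n_restarts=2, max_iter=150)
        cv2 = cv_choose_k(sub, [1, 2], folds=2, seed=7, n_restarts=2, max_iter=150)
        assert cv1.errors == cv2.errors

    def test_empty_k_range_rejected(self, small_sim):
        gm, _, _ = small_sim
        with pytest.raises(ValueError):
            cv_choose_k(gm, [], folds=2)
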
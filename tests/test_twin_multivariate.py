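"""Cholesky twin decomposition: reductions, recovery, order invariance."""

import numpy as np
import pytest

import twintraj as tt
from twintraj.synthetic import SimulationConfig, _component_paths
from twintraj.twin_multivariate import CholeskyFit, MultiTraitPairData


@pytest.fixture(scope="module")
def two_trait_cohort():
    """rA = 0.6, rE = 0.1, a2 = 0.6 per trait, 2000 pairs per group."""
    ra = np.array([[1.0, 0.6], [0.6, 1.0]])
    re = np.array([[1.0, 0.1], [0.1, 1.0]])
    a2 = np.array([0.6, 0.6])
    cfg = SimulationConfig(
        n_pairs_per_group={"MZM": 2000, "DZM": 2000},
        trait_labels=("t1", "t2"),
        true_paths_A=_component_paths(np.ones(2), a2, ra),
        true_paths_E=_component_paths(np.ones(2), 1 - a2, re),
        wave_ages=[],
        seed=7,
    )
    return tt.simulate_cohort(cfg)


@pytest.fixture(scope="module")
def two_trait_fit(two_trait_cohort):
    groups = tt.multitrait_from_table(two_trait_cohort.traits, ("t1", "t2"))
    return tt.fit_cholesky(groups)


class TestFitCholesky:
    def test_k1_reduces_to_univariate(self, ae_cohort):
        groups1 = tt.twin_groups_from_table(ae_cohort.traits, "trait")
        uni = tt.fit_variance_components(
            groups1, tt.ModelSpec("AE", "common")
        )
        groups = tt.multitrait_from_table(ae_cohort.traits, ("trait",))
        chol = tt.fit_cholesky(groups)
        a2 = chol.component_cov("A")[0, 0] / chol.sigma_total[0, 0]
        assert a2 == pytest.approx(uni.shares["M"]["A"], abs=1e-6)
        assert chol.minus2LL == pytest.approx(uni.minus2LL, abs=1e-6)

    def test_two_trait_recovery(self, two_trait_fit):
        corr = tt.derive_correlations(two_trait_fit)
        assert abs(corr["r_A"][0, 1] - 0.6) < 0.07
        assert abs(corr["r_E"][0, 1] - 0.1) < 0.07
        a2 = np.diag(two_trait_fit.component_cov("A")) / np.diag(
            two_trait_fit.sigma_total
        )
        assert np.all(np.abs(a2 - 0.6) < 0.07)

    def test_independent_traits_give_null_cross_correlations(self):
        cfg = SimulationConfig(
            n_pairs_per_group={"MZM": 2000, "DZM": 2000},
            trait_labels=("t1", "t2"),
            true_paths_A=np.diag([0.8, 0.8]),
            true_paths_E=np.diag([0.6, 0.6]),
            wave_ages=[],
            seed=17,
        )
        coh = tt.simulate_cohort(cfg)
        fit = tt.fit_cholesky(tt.multitrait_from_table(coh.traits, ("t1", "t2")))
        corr = tt.derive_correlations(fit)
        for key in ("r_A", "r_E"):
            assert abs(corr[key][0, 1]) < 3.0 / np.sqrt(4000)

    def test_trait_reordering_leaves_implied_covariances(self, two_trait_cohort):
        t = two_trait_cohort.traits
        fit_ab = tt.fit_cholesky(tt.multitrait_from_table(t, ("t1", "t2")))
        fit_ba = tt.fit_cholesky(tt.multitrait_from_table(t, ("t2", "t1")))
        perm = np.array([[0, 1], [1, 0]])
        for comp in ("A", "E"):
            back = perm @ fit_ba.component_cov(comp) @ perm.T
            assert np.allclose(back, fit_ab.component_cov(comp), atol=1e-6)

    def test_structural_cross_twin_covariances(self, two_trait_fit):
        from twintraj.twin_multivariate import _expected_cov

        k = two_trait_fit.k
        tris = two_trait_fit.paths
        mz = _expected_cov(tris, "MZ", two_trait_fit.components)
        dz = _expected_cov(tris, "DZ", two_trait_fit.components)
        sig_a = two_trait_fit.component_cov("A")
        assert np.allclose(mz[:k, k:], sig_a)
        assert np.allclose(dz[:k, k:], 0.5 * sig_a)

    def test_missing_e_component_rejected(self, two_trait_cohort):
        groups = tt.multitrait_from_table(two_trait_cohort.traits, ("t1", "t2"))
        with pytest.raises(ValueError, match="mandatory"):
            tt.fit_cholesky(groups, components=("A",))


def _manual_fit(sig_a, sig_e, labels=("x", "y")):
    return CholeskyFit(
        trait_labels=labels,
        components=("A", "E"),
        paths={"A": np.linalg.cholesky(sig_a), "E": np.linalg.cholesky(sig_e)},
        means=np.zeros(len(labels)),
        minus2LL=0.0,
        n_free_params=0,
        converged=True,
        fingerprint="manual",
    )


class TestDerivedQuantities:
    def test_unit_diagonal(self, two_trait_fit):
        corr = tt.derive_correlations(two_trait_fit)
        for key in ("r_A", "r_E", "r_phenotypic"):
            assert np.allclose(np.diag(corr[key]), 1.0)

    def test_hand_arithmetic_correlation(self):
        fit = _manual_fit(np.array([[4.0, 2.0], [2.0, 4.0]]), np.eye(2))
        corr = tt.derive_correlations(fit)
        assert corr["r_A"][0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_phenotypic_r_matches_sample_pearson(self, two_trait_cohort,
                                                 two_trait_fit):
        corr = tt.derive_correlations(two_trait_fit)
        t = two_trait_cohort.traits
        sample = np.corrcoef(t["t1"], t["t2"])[0, 1]
        assert abs(corr["r_phenotypic"][0, 1] - sample) < 0.02

    def test_diagonal_environment_makes_cross_covariance_fully_genetic(self):
        sig_a = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = _manual_fit(sig_a, np.diag([0.5, 0.5]))
        dec = tt.decompose_phenotypic_correlation(fit, 0, 1)
        assert dec["A"] == pytest.approx(1.0, abs=1e-12)
        assert dec["E"] == pytest.approx(0.0, abs=1e-12)

    def test_contributions_sum_to_one(self, two_trait_fit):
        dec = tt.decompose_phenotypic_correlation(two_trait_fit, 0, 1)
        assert sum(dec.values()) == pytest.approx(1.0, abs=1e-10)

    def test_same_trait_decomposition_rejected(self, two_trait_fit):
        with pytest.raises(ValueError, match="distinct"):
            tt.decompose_phenotypic_correlation(two_trait_fit, 1, 1)

    def test_correlation_ci_brackets_estimate(self, two_trait_fit):
        corr = tt.derive_correlations(two_trait_fit)
        r = corr["r_A"][0, 1]
        lo, hi, method = tt.correlation_ci(two_trait_fit, "A", 0, 1,
                                           method="delta")
        assert method.startswith("delta")
        assert lo < r < hi
        assert hi - lo < 0.3  # informative at n=2000/group


class TestDataContainers:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="n x 4"):
            MultiTraitPairData("MZM", np.zeros((5, 3)), ("a", "b"))

    def test_mixed_trait_counts_rejected(self, two_trait_cohort, ae_cohort):
        g2 = tt.multitrait_from_table(two_trait_cohort.traits, ("t1", "t2"))
        g1 = tt.multitrait_from_table(ae_cohort.traits, ("trait",))
        with pytest.raises(ValueError, match="same traits"):
            tt.fit_cholesky(g2 + g1)
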
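"""Univariate twin modeling: FIML correctness, oracles, sex limitation, CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twintraj as tt
from twintraj import _fiml
from twintraj.synthetic import SimulationConfig
from twintraj.twin_univariate import (
    ModelSpec,
    TwinGroupData,
    fit_constrained_saturated,
)


def _direct_neg2ll(data, mean, cov):
    """Row-by-row FIML -2LL using scipy densities (independent oracle)."""
    total = 0.0
    for row in np.asarray(data, dtype=float):
        obs = ~np.isnan(row)
        if not obs.any():
            continue
        x = row[obs]
        m = np.asarray(mean)[obs]
        s = np.asarray(cov)[np.ix_(obs, obs)]
        total += -2.0 * stats.multivariate_normal.logpdf(x, m, s)
    return total


class TestFimlEngine:
    def test_pattern_compression_matches_row_loop(self, rng):
        data = rng.normal(0, 1, (40, 2))
        data[rng.random((40, 2)) < 0.3] = np.nan
        data = data[~np.isnan(data).all(axis=1)]
        mean = np.array([0.3, -0.2])
        cov = np.array([[1.4, 0.5], [0.5, 0.9]])
        pats = _fiml.compress(data)
        assert _fiml.neg2ll(pats, mean, cov) == pytest.approx(
            _direct_neg2ll(data, mean, cov), rel=1e-12
        )

    def test_zero_missingness_equals_complete_data_likelihood(self, rng):
        data = rng.normal(0, 1, (60, 2))
        pats = _fiml.compress(data)
        assert len(pats) == 1
        mean = np.zeros(2)
        cov = np.array([[1.0, 0.4], [0.4, 1.2]])
        assert _fiml.neg2ll(pats, mean, cov) == pytest.approx(
            _direct_neg2ll(data, mean, cov), rel=1e-12
        )


class TestSaturated:
    def test_closed_form_value(self, ae_groups):
        sat = tt.fit_saturated(ae_groups)
        for g in ae_groups:
            gs = sat.groups[g.group]
            assert gs.minus2ll == pytest.approx(
                _direct_neg2ll(g.pairs, gs.mean, gs.cov), rel=1e-10
            )
            # n (2 log 2pi + log det S + 2) identity for complete data
            n = g.n_pairs
            expected = n * (
                2 * np.log(2 * np.pi) + np.linalg.slogdet(gs.cov)[1] + 2
            )
            assert gs.minus2ll == pytest.approx(expected, rel=1e-10)

    def test_row_permutation_invariance(self, ae_groups, rng):
        sat1 = tt.fit_saturated(ae_groups)
        shuffled = [
            TwinGroupData(g.group, rng.permutation(g.pairs, axis=0), g.trait)
            for g in ae_groups
        ]
        sat2 = tt.fit_saturated(shuffled)
        assert sat1.minus2LL == pytest.approx(sat2.minus2LL, abs=1e-8)

    def test_identical_cotwins_flagged_degenerate(self, rng):
        vals = rng.normal(0, 1, 30)
        g = TwinGroupData("MZM", np.column_stack([vals, vals]))
        sat = tt.fit_saturated([g])
        gs = sat.groups["MZM"]
        assert gs.degenerate
        assert gs.correlation == pytest.approx(1.0, abs=1e-10)

    def test_fiml_with_partial_pairs(self, rng):
        full = rng.normal(0, 1, (200, 2))
        full[:, 1] = 0.6 * full[:, 0] + 0.8 * rng.normal(0, 1, 200)
        data = full.copy()
        data[:30, 1] = np.nan
        g = TwinGroupData("MZM", data)
        sat = tt.fit_saturated([g])
        gs = sat.groups["MZM"]
        assert sat.minus2LL == pytest.approx(
            _direct_neg2ll(data, gs.mean, gs.cov), rel=1e-8
        )


class TestVarianceComponents:
    def test_ae_matches_falconer_oracle(self, ae_groups):
        # the moment estimator carries sampling SD ~0.06 at 1000 pairs/group;
        # the tight asymptotic comparison lives in the acceptance suite
        fit = tt.fit_variance_components(ae_groups, ModelSpec("AE", "common"))
        m = tt.moment_estimates(ae_groups)
        falconer = np.clip(2.0 * (m["rMZ"] - m["rDZ"]), 0.0, 1.0)
        assert abs(fit.shares["M"]["A"] - falconer) < 0.15

    def test_shares_sum_to_one(self, ae_groups):
        fit = tt.fit_variance_components(ae_groups, ModelSpec("ACE", "common"))
        for sex in ("M", "F"):
            assert sum(fit.shares[sex].values()) == pytest.approx(1.0, abs=1e-8)

    def test_ce_data_fit_with_ace(self):
        cfg = tt.single_trait_config(
            0.0, 0.5, n_pairs=2000, groups=("MZM", "DZM"), seed=71
        )
        coh = tt.simulate_cohort(cfg)
        groups = tt.twin_groups_from_table(coh.traits, "trait")
        fit = tt.fit_variance_components(groups, ModelSpec("ACE", "common"))
        assert fit.shares["M"]["A"] < 0.05
        assert abs(fit.shares["M"]["C"] - 0.5) < 0.05

    def test_e_only_reduces_to_independent_normals(self, ae_groups):
        fit = tt.fit_variance_components(ae_groups, ModelSpec("E", "common"))
        values = np.concatenate([g.pairs.ravel() for g in ae_groups])
        values = values[~np.isnan(values)]
        mu, var = values.mean(), values.var()
        expected = len(values) * (np.log(2 * np.pi) + np.log(var) + 1.0)
        assert fit.minus2LL == pytest.approx(expected, abs=1e-5)

    def test_nested_models_ordered_by_likelihood(self, ae_groups):
        sat = tt.fit_saturated(ae_groups)
        ace = tt.fit_variance_components(ae_groups, ModelSpec("ACE", "sex_specific"))
        ae = tt.fit_variance_components(ae_groups, ModelSpec("AE", "common"))
        e = tt.fit_variance_components(ae_groups, ModelSpec("E", "common"))
        assert sat.minus2LL <= ace.minus2LL + 1e-4
        assert ace.minus2LL <= ae.minus2LL + 1e-4
        assert ae.minus2LL <= e.minus2LL + 1e-4

    def test_relabeling_twins_leaves_estimates_unchanged(self, ae_groups):
        fit1 = tt.fit_variance_components(ae_groups, ModelSpec("AE", "common"))
        swapped = [
            TwinGroupData(g.group, g.pairs[:, ::-1].copy(), g.trait)
            for g in ae_groups
        ]
        fit2 = tt.fit_variance_components(swapped, ModelSpec("AE", "common"))
        assert fit1.shares["M"]["A"] == pytest.approx(
            fit2.shares["M"]["A"], abs=1e-6
        )

    def test_single_zygosity_rejected(self, ae_groups):
        mz_only = [g for g in ae_groups if g.zygosity == "MZ"]
        with pytest.raises(ValueError, match="not identified"):
            tt.fit_variance_components(mz_only, ModelSpec("AE", "common"))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="simultaneously"):
            ModelSpec("ACDE")
        with pytest.raises(ValueError, match="mandatory"):
            ModelSpec("AC")


@pytest.fixture(scope="module")
def sexlim_cohort():
    # male genetic path twice the female one, equal totals otherwise
    cfg = SimulationConfig(
        n_pairs_per_group={g: 1000 for g in ("MZM", "MZF", "DZM", "DZF", "DZOS")},
        trait_labels=("trait",),
        true_paths_A={"M": np.array([[1.6]]), "F": np.array([[0.8]])},
        true_paths_E={"M": np.array([[0.9]]), "F": np.array([[0.9]])},
        wave_ages=[],
        seed=81,
    )
    return tt.simulate_cohort(cfg)


class TestSexLimitation:
    def test_sex_specific_model_detects_genetic_difference(self, sexlim_cohort):
        groups = tt.twin_groups_from_table(sexlim_cohort.traits, "trait")
        full = tt.fit_variance_components(groups, ModelSpec("AE", "sex_specific"))
        nosex = tt.fit_variance_components(groups, ModelSpec("AE", "common"))
        cmp_ = tt.compare_models([nosex], full)
        p = cmp_.table.set_index("model").loc["AE/common", "p"]
        assert p < 0.01
        assert full.paths["A"]["M"] > full.paths["A"]["F"]

    def test_equal_a_recovers_common_genetic_path(self, ae_cohort):
        groups = tt.twin_groups_from_table(ae_cohort.traits, "trait")
        fit = tt.fit_variance_components(groups, ModelSpec("AE", "equal_a"))
        assert fit.paths["A"]["M"] == pytest.approx(fit.paths["A"]["F"], abs=1e-10)


class TestAssumptionsAndComparison:
    def test_assumption_test_flags_mean_shift(self):
        cfg = tt.single_trait_config(
            0.6, n_pairs=500, groups=("MZM", "DZM"), seed=91
        )
        coh = tt.simulate_cohort(cfg)
        traits = coh.traits.copy()
        traits.loc[traits["birth_order"] == 2, "trait"] += 5.0
        groups = tt.twin_groups_from_table(traits, "trait")
        cmp_ = tt.test_assumptions(groups)
        p = cmp_.table.set_index("model").loc[
            "saturated (equal means/variances)", "p"
        ]
        assert p < 1e-3

    def test_reference_vs_itself_is_null(self, ae_groups):
        sat = tt.fit_saturated(ae_groups)
        cmp_ = tt.compare_models([sat], sat)
        row = cmp_.table.iloc[0]
        assert row["delta_minus2LL"] == 0.0
        assert row["delta_df"] == 0
        assert row["p"] == 1.0

    def test_mismatched_data_rejected(self, ae_groups):
        sat = tt.fit_saturated(ae_groups)
        other = tt.simulate_cohort(
            tt.single_trait_config(0.5, n_pairs=100, groups=("MZM", "DZM"), seed=99)
        )
        fit = tt.fit_variance_components(
            tt.twin_groups_from_table(other.traits, "trait"),
            ModelSpec("AE", "common"),
        )
        with pytest.raises(ValueError, match="fingerprint"):
            tt.compare_models([fit], sat)

    def test_selection_prefers_parsimony(self, ae_groups):
        sat = tt.fit_saturated(ae_groups)
        ace = tt.fit_variance_components(ae_groups, ModelSpec("ACE", "common"))
        ae = tt.fit_variance_components(ae_groups, ModelSpec("AE", "common"))
        cmp_ = tt.compare_models([ace, ae], sat)
        # data are AE; the 3-parameter AE model should win on parsimony
        assert cmp_.selected == "AE/common"


class TestProfileCI:
    def test_ci_brackets_estimate_and_nests(self, ae_groups):
        fit = tt.fit_variance_components(ae_groups, ModelSpec("AE", "common"))
        ci95 = tt.profile_ci(fit, ("A", "M"), level=0.95)
        ci99 = tt.profile_ci(fit, ("A", "M"), level=0.99)
        a2 = fit.shares["M"]["A"]
        assert ci95.lower < a2 < ci95.upper
        assert ci99.lower <= ci95.lower and ci95.upper <= ci99.upper

    def test_boundary_share_flagged(self):
        cfg = tt.single_trait_config(
            0.0, n_pairs=400, groups=("MZM", "DZM"), seed=101
        )
        coh = tt.simulate_cohort(cfg)
        groups = tt.twin_groups_from_table(coh.traits, "trait")
        fit = tt.fit_variance_components(groups, ModelSpec("AE", "common"))
        if fit.shares["M"]["A"] < 1e-4:
            ci = tt.profile_ci(fit, ("A", "M"))
            assert ci.lower == 0.0
            assert ci.lower_at_boundary

    def test_constrained_saturated_nested_in_saturated(self, ae_groups):
        sat = tt.fit_saturated(ae_groups)
        con = fit_constrained_saturated(ae_groups)
        assert con.minus2LL >= sat.minus2LL - 1e-6
        assert con.n_free_params < sat.n_free_params
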
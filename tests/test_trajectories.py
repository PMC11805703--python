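"""Growth-model contracts: completeness filter, REML recovery, BLUP behavior."""

import numpy as np
import pandas as pd
import pytest

import twintraj as tt
from twintraj.trajectories import NoEligibleIndividualsError


def _line_table(rng, n=40, residual_sd=1e-4, ages=(17.5, 24.0, 37.0),
                intercepts=None, slopes=None):
    if intercepts is None:
        intercepts = rng.normal(22.0, 1.5, n)
    if slopes is None:
        slopes = rng.normal(0.24, 0.05, n)
    rows = []
    for i in range(n):
        for w, age in enumerate(ages, start=3):
            rows.append(
                {
                    "individual_id": f"I{i:03d}",
                    "sex": "M",
                    "wave": w,
                    "age": age,
                    "bmi": intercepts[i] + slopes[i] * (age - 17.5)
                    + rng.normal(0, residual_sd),
                }
            )
    return pd.DataFrame(rows), intercepts, slopes


class TestSelectCompleteIndividuals:
    def test_complete_table_is_unchanged(self, rng):
        df, _, _ = _line_table(rng, n=10)
        out = tt.select_complete_individuals(df, (3, 4, 5))
        pd.testing.assert_frame_equal(out, df)

    def test_direct_filter_count(self, rng):
        df, _, _ = _line_table(rng, n=10)
        drop = df["individual_id"].isin([f"I{i:03d}" for i in range(4)])
        df.loc[drop & (df["wave"] == 5), "bmi"] = np.nan
        out = tt.select_complete_individuals(df, (3, 4, 5))
        assert out["individual_id"].nunique() == 6

    def test_independent_missingness_retention_rate(self):
        cfg = tt.default_config(
            seed=77, missing_rate=0.3,
            n_pairs_per_group={"MZM": 250, "MZF": 250, "DZM": 250, "DZF": 250},
        )
        coh = tt.simulate_cohort(cfg)
        n_all = coh.traits.shape[0]
        out = tt.select_complete_individuals(coh.phenotypes, (3, 4, 5))
        frac = out["individual_id"].nunique() / n_all
        p = 0.7**3
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n_all)

    def test_no_eligible_individuals_is_explicit(self, rng):
        df, _, _ = _line_table(rng, n=5)
        df.loc[df["wave"] == 5, "bmi"] = np.nan
        with pytest.raises(NoEligibleIndividualsError):
            tt.select_complete_individuals(df, (3, 4, 5))


class TestGrowthModel:
    def test_noise_free_recovery(self, rng):
        df, intercepts, slopes = _line_table(rng, n=60)
        fits = tt.fit_growth_model(df, by_sex=False)
        fit = fits["all"]
        assert fit.converged
        assert abs(fit.fixed_intercept - intercepts.mean()) < 1e-3
        assert abs(fit.fixed_slope - slopes.mean()) < 1e-3
        traj = tt.extract_individual_trajectories(fits, df)
        merged = traj.sort_values("individual_id")
        assert np.allclose(merged["intercept"], intercepts, atol=1e-3)
        assert np.allclose(merged["slope"], slopes, atol=1e-3)

    def test_simulated_cohort_slope_recovery(self):
        cfg = tt.default_config(
            seed=13, n_pairs_per_group={"MZM": 125, "DZM": 125}
        )
        coh = tt.simulate_cohort(cfg)
        adult = coh.phenotypes[coh.phenotypes["wave"].isin((3, 4, 5))]
        fit = tt.fit_growth_model(adult, by_sex=False)["all"]
        true_mean_slope = coh.traits["slope"].mean()
        se = coh.traits["slope"].std() / np.sqrt(len(coh.traits))
        assert abs(fit.fixed_slope - true_mean_slope) < 3 * se

    def test_ols_method_matches_pooled_least_squares(self, rng):
        df, _, _ = _line_table(rng, n=30, residual_sd=1.0)
        fit = tt.fit_growth_model(df, by_sex=False, method="ols")["all"]
        x = df["age"].to_numpy() - 17.5
        slope, intercept = np.polyfit(x, df["bmi"].to_numpy(), 1)
        assert abs(fit.fixed_intercept - intercept) < 1e-6
        assert abs(fit.fixed_slope - slope) < 1e-6

    def test_fewer_than_three_observations_rejected(self, rng):
        df, _, _ = _line_table(rng, n=10)
        df = df[~((df["individual_id"] == "I000") & (df["wave"] == 5))]
        with pytest.raises(ValueError, match="3 observations"):
            tt.fit_growth_model(df, by_sex=False)

    def test_likelihood_invariant_to_row_order(self, rng):
        df, _, _ = _line_table(rng, n=30, residual_sd=1.0)
        fit1 = tt.fit_growth_model(df, by_sex=False)["all"]
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        fit2 = tt.fit_growth_model(shuffled, by_sex=False)["all"]
        assert np.isclose(fit1.log_likelihood, fit2.log_likelihood, atol=1e-6)


class TestBlups:
    def test_blups_shrink_relative_to_per_individual_ols(self, rng):
        df, _, _ = _line_table(rng, n=80, residual_sd=1.5)
        fits = tt.fit_growth_model(df, by_sex=False)
        traj = tt.extract_individual_trajectories(fits, df)
        ols = tt.per_individual_ols(df)
        assert traj["intercept"].var() <= ols["intercept"].var() + 1e-9
        assert traj["slope"].var() <= ols["slope"].var() + 1e-9

    def test_blup_means_match_fixed_effects(self, rng):
        df, _, _ = _line_table(rng, n=80, residual_sd=1.5)
        fits = tt.fit_growth_model(df, by_sex=False)
        traj = tt.extract_individual_trajectories(fits, df)
        fit = fits["all"]
        assert abs(traj["intercept"].mean() - fit.fixed_intercept) < 5e-3
        assert abs(traj["slope"].mean() - fit.fixed_slope) < 5e-3

    def test_exact_line_individual_recovered(self, rng):
        df, intercepts, slopes = _line_table(rng, n=30)
        target = df["individual_id"] == "I000"
        df.loc[target, "bmi"] = 22.0 + 0.3 * (df.loc[target, "age"] - 17.5)
        fits = tt.fit_growth_model(df, by_sex=False)
        traj = tt.extract_individual_trajectories(fits, df)
        row = traj[traj["individual_id"] == "I000"].iloc[0]
        assert abs(row["intercept"] - 22.0) < 1e-3
        assert abs(row["slope"] - 0.3) < 1e-3

    def test_by_sex_fit_preserves_individuals(self, default_cohort):
        pheno = default_cohort.phenotypes
        adult = pheno[pheno["wave"].isin((3, 4, 5))]
        fits = tt.fit_growth_model(adult, by_sex=True)
        traj = tt.extract_individual_trajectories(fits, adult)
        assert set(traj["individual_id"]) == set(adult["individual_id"])
        assert len(traj) == adult["individual_id"].nunique()
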
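# Methods

`twintraj` implements the quantitative-genetic analysis of longitudinal BMI in
twins: per-individual growth trajectories from a linear mixed model, univariate
twin variance decomposition with sex limitation, a multivariate Cholesky
decomposition yielding genetic and environmental correlations, and
polygenic-score (PRS) correlation analysis. Because the motivating cohort data
(FinnTwin12) are access-restricted, every stage is exercised on synthetic twin
cohorts whose generating architecture is known exactly; the generator is
first-class, tested code, not a fixture.

## The synthetic cohort

Five zygosity-by-sex groups are generated: monozygotic male/female (MZM, MZF),
same-sex dizygotic (DZM, DZF) and opposite-sex dizygotic (DZOS) pairs. For k
traits, each individual's trait vector is

    y = mu_sex + T_A a + T_C c + T_E e,     a, c, e ~ N(0, I_k),

with lower-triangular loading matrices `T_X` (optionally sex-specific), so the
implied component covariances `Sigma_X = T_X T_X'` are positive semi-definite
by construction. Additive-genetic latents are identical within MZ pairs and
correlate 0.5 within DZ pairs, realized constructively as
`sqrt(0.5) * shared + sqrt(0.5) * own` (identical in distribution to the joint
multivariate-normal draw, simpler to verify). Shared-environment latents are
identical within pairs; unique-environment latents are independent. Dominance
generation is not implemented (the analyses this package targets select AE
models); the config reserves a `true_paths_D` slot.

Default conditions mirror the published descriptives of the emulated cohort:

* traits `(bmi11.5, bmi14, intercept, slope)` with sex-specific means
  (17.71/17.54, 19.34/19.35, 21.77/20.99 kg/m², 0.24/0.22 kg/m² per year) and
  SDs (2.55/2.58, 2.67/2.63, 2.80/2.74, 0.07/0.12);
* AE architecture with standardized genetic shares 0.84, 0.84, 0.81/0.78,
  0.63/0.64 (men/women) and the published genetic/environmental cross-trait
  correlations; the bmi11.5–bmi14 entries are not published for this cohort
  and are set once to r_A = 0.80, r_E = 0.40, values typical of adjacent-age
  BMI in longitudinal twin data (positive-definiteness verified);
* five survey waves at mean ages 11.42, 14.05, 17.62, 24.22, 37.17 years with
  age jitter truncated at ±3 SD, matching the published age SDs;
* 100 pairs per group (the study's ~494 complete pairs spread over five
  groups); tests and the acceptance script state their own sizes where larger
  cohorts are simulated for stability.

Adolescent waves record the corresponding bmi trait directly; adult waves
(mean age ≥ 17.5) are generated from each individual's latent (intercept,
slope) as `bmi(age) = intercept + slope (age - 17.5) + N(0, 0.5)`. The 0.5
kg/m² observation noise corresponds to the ~0.97 reliability of self-reported
BMI at these trait SDs. The PRS is generated at the score level,
`lambda * a_1 + sqrt(1 - lambda^2) * noise` with default loading
`lambda = 0.35` on the first genetic factor, then standardized; ten principal
components are independent standard normals (the generator emulates a cohort
already corrected for stratification, so the PCs carry no real structure —
passing PRS tests therefore shows the residualization machinery is correct,
not that stratification in real data is handled).

What the generator does not emulate: nonlinear BMI trajectories, informative
(BMI-dependent) missingness, assortative mating, sibling interaction,
measurement-error correlation within pairs, and real LD-derived PC structure.
Passing tests demonstrate correct recovery of the stated generating model, not
robustness to these violations.

## Growth trajectories

BMI over the adult waves (17.5–37 years) is modeled per sex as

    bmi_ij = b0 + b1 (age_ij - 17.5) + u0_i + u1_i (age_ij - 17.5) + e_ij,

random intercept and slope per individual, fit by REML (ML and a pooled-OLS
degenerate mode are available) via statsmodels MixedLM with fallback
optimizers. Individuals need all three adult waves (the completeness filter is
its own, logged, stage). Per-individual intercepts (model BMI at the 17.5-year
centering age) and slopes are fixed effects plus empirical-Bayes (BLUP)
deviations; BLUPs shrink toward the population line relative to per-individual
least squares, which a test asserts. Twin clustering is deliberately absent
from this stage — the trajectory estimates feed twin models downstream, which
is where family structure belongs; adding a family level here would change
the BLUPs only marginally at these residual variances.

## Univariate twin models

For each trait, the five groups' pair vectors are modeled as bivariate normal
with expected moments assembled from path coefficients: within-person variance
`a² + c² (or d²) + e²`, cross-twin covariance `kappa_A a a' + kappa_C c c'`
with `kappa_A = 1 (MZ) / 0.5 (DZ)`, `kappa_C = 1`, `kappa_D = 1 / 0.25`, and
primes marking the co-twin's (possibly sex-specific) paths, so DZOS pairs
contribute `0.5 a_M a_F`. The likelihood is full-information maximum
likelihood: rows are compressed into per-missingness-pattern sufficient
statistics (count, sum, sum of outer products), after which each -2LL
evaluation is O(#patterns) regardless of sample size and coincides exactly
with the complete-data Gaussian likelihood when nothing is missing.

Sex-limitation submodels (the published workflow names but does not define
them; these definitions are this package's):

* full (`sex_specific`): means and all paths free per sex, DZOS genetic
  correlation fixed at 0.5;
* no sex differences (`common`): all parameters equated across sexes;
* no sex-specific genetic effects (`equal_a`): the genetic path equated,
  means and the remaining paths free per sex.

The saturated model frees all five moments per group (closed-form MLE for
complete data; numeric FIML otherwise); its constrained variant equates means
and variances across co-twins, giving the standard assumption test against
the saturated reference. Assumption violations are reported, never fatal.
Model comparison uses -2LL differences against chi-square with the parameter
difference as df; selection takes the most parsimonious model not
significantly worse than the reference at alpha = 0.05, AIC breaking ties.
Testing a variance component on its zero boundary makes the naive 1-df LRT
conservative (rejection ~2.5% at nominal 5%); the naive p-value is the
default to mirror common practice, with the 50:50 chi-square mixture
available (`boundary="mixture"`).

Numerics: optimization is quasi-Newton (BFGS, gradient tolerance 1e-8) on the
unconstrained path scale — paths are sign-unidentified, so absolute values
are reported and all inference is on standardized shares — started from
Falconer moment estimates (`a² = 2(rMZ - rDZ)` clipped to (0.02, 0.95)), with
up to five jittered restarts and a short Nelder-Mead polish. Degenerate
inputs: a group with twin1 ≡ twin2 yields a singular saturated covariance and
is flagged, not raised; an all-missing trait is an error.

Profile-likelihood confidence intervals for a standardized share fix the
share at a candidate value, re-optimize all nuisance parameters (by
reparametrizing the profiled stratum as log total variance plus
remaining-share logits; equality-constrained SLSQP for the `equal_a` mode,
whose genetic path spans strata), and root-bracket where -2LL rises by the
chi-square(1) quantile. Bounds that cannot be bracketed inside (0, 1) are
reported at the boundary with a flag. Coverage for a true share of 0.8 at 500
pairs is verified to sit in [0.90, 0.98] over 500 replicates.

## Multivariate Cholesky decomposition

For k traits (default order bmi11.5, bmi14, intercept, slope — order affects
the triangular factors, not the implied covariances, which a test asserts),
lower-triangular `T_A` and `T_E` (optionally `T_C`) parametrize component
covariances; the expected 2k x 2k pair covariance stacks the phenotypic
`Sigma` on the diagonal and `kappa_A Sigma_A + kappa_C Sigma_C` off it.
Standardizing `Sigma_X` gives the genetic (r_A) and environmental (r_E)
correlations; standardizing the total gives model-implied phenotypic
correlations; `Sigma_X[i,j] / Sigma[i,j]` decomposes each cross-trait
covariance into component contributions (summing to 1 exactly).

The FIML objective has an analytic gradient (per pattern,
`d(-2LL)/dSigma = n G - G M G` chained onto the triangular factors), which
makes the 24-parameter four-trait fit take well under a second; start values
come from cross-twin moment matrices (`Sigma_A ~ 2(C_MZ - C_DZ)`) projected
to positive definiteness. Per-sex analyses fit that sex's MZ and DZ groups;
opposite-sex pairs are excluded from per-sex multivariate fits. Correlation
CIs: profile likelihood (`correlation_ci(..., method="profile")`) or the
delta method on the Fisher-z scale; the pipeline's report table uses the
delta method, labeled, because profiling all 36 correlations of a four-trait
model per run costs far more than it informs. When a component variance is
zero the corresponding correlations are undefined and reported missing.

## PRS analysis

The raw score is regressed on PC1–PC10 with a family random intercept
(statsmodels MixedLM); conditional (within-family) residuals — the family
effect is a stratification nuisance, so removing it is the default, with
marginal residuals available — are standardized to mean 0, variance 1
(sample SD, n−1) exactly. Correlations with traits are Pearson r with
Fisher-z CIs, labeled weak [0, 0.40) / moderate [0.40, 0.60) / strong
[0.60, 1] (the published bins leave (0.39, 0.40) and (0.59, 0.60) unassigned;
half-open intervals close the gap). Twin non-independence is ignored in the
default CIs, matching the emulated workflow; a cluster-robust variant would
be a labeled extension. Distribution comparisons use the two-sample
Kolmogorov–Smirnov test, exact p when `n1 * n2 <= 10^4`, asymptotic
otherwise.

By construction `corr(PRS, trait) -> lambda * a * (T_A[i,1] / (a_i sd_i))`,
so for the first trait the correlation converges to `lambda * a_1`, which the
acceptance suite checks; for later traits the score correlates only through
their loading on the first genetic factor, so those correlations are
attenuated relative to a score built on the whole genetic value — a known
property of the single-factor score construction, not a bug.

## Pipeline

`run_pipeline` executes simulate/ingest → completeness filter → growth model
→ four-trait join → descriptives/ICC → univariate models (per trait, all
component-set x sex-mode combinations, compared against the saturated model)
→ per-sex Cholesky → PRS, writing each table plus a manifest (config hash,
per-stage counts and -2LLs, sha256 file checksums). Identical config and seed
reproduce identical checksums; the output directory and log level are
excluded from the config hash since they do not affect results. Failures in
optional downstream stages are recorded without discarding completed outputs.
Individuals missing any of the four traits are excluded from the Cholesky
stage only (per-stage completeness).

## Known limitations

* Linear trajectories only; no nonlinear or spline growth models.
* No dominance generation, gene–environment interaction, rater models, or
  extended pedigrees; C and D cannot be estimated simultaneously (twins
  reared together).
* ICC per the standard one-way ANOVA estimator; negative estimates are
  reported as-is.
* The naive boundary LRT is conservative for variance components at zero.
* KS p-values and Pearson CIs treat twins as independent observations.
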
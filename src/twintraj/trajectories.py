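"""Adult BMI growth model: random intercept + slope, per-individual BLUPs.

BMI over the adult waves is modeled as

    bmi_ij = b0 + b1 (age_ij - center) + u0_i + u1_i (age_ij - center) + eps_ij

with (u0, u1) ~ N(0, G) per individual and eps ~ N(0, sigma2).  The fixed
effects give the population trajectory; each individual's intercept (model BMI
at the centering age, default 17.5 years) and slope (kg/m^2 per year) are the
fixed effects plus the empirical-Bayes (BLUP) deviations.

Fitting is delegated to statsmodels MixedLM (REML by default, ML optional),
with fallback optimizers on non-convergence.  Twin clustering is deliberately
not modeled here: the trajectory estimates feed twin models downstream, which
is where the family structure is handled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


class NoEligibleIndividualsError(ValueError):
    pass


@dataclass
class GrowthModelFit:
    fixed_intercept: float
    fixed_slope: float
    random_effects_cov: np.ndarray   # 2x2, (intercept, slope) deviations
    residual_variance: float
    n_individuals: int
    n_observations: int
    log_likelihood: float
    converged: bool
    center_age: float
    method: str                      # "reml", "ml" or "ols"
    blups: pd.DataFrame | None = None  # individual_id, intercept, slope


def select_complete_individuals(
    long_table: pd.DataFrame, required_waves=(3, 4, 5)
) -> pd.DataFrame:
    """Keep only individuals with a non-missing BMI at every required wave."""
    required = set(required_waves)
    present = set(long_table["wave"].unique())
    missing_waves = required - present
    if missing_waves:
        raise NoEligibleIndividualsError(
            f"waves {sorted(missing_waves)} absent from the table"
        )
    ok = long_table.dropna(subset=["bmi"])
    counts = (
        ok[ok["wave"].isin(required)]
        .groupby("individual_id")["wave"]
        .nunique()
    )
    eligible = set(counts[counts == len(required)].index)
    n_all = long_table["individual_id"].nunique()
    n_removed = n_all - len(eligible)
    if not eligible:
        raise NoEligibleIndividualsError(
            f"no individuals have BMI at all required waves {sorted(required)}"
        )
    logger.info(
        "select_complete_individuals: retained %d of %d individuals (%d removed)",
        len(eligible), n_all, n_removed,
    )
    return long_table[long_table["individual_id"].isin(eligible)].copy()


def _fit_one(data: pd.DataFrame, center_age: float, method: str) -> GrowthModelFit:
    d = data.dropna(subset=["bmi", "age"]).copy()
    obs_per_ind = d.groupby("individual_id").size()
    if (obs_per_ind < 3).any():
        bad = obs_per_ind[obs_per_ind < 3].index[:5].tolist()
        raise ValueError(
            f"random intercept + slope + residual need >=3 observations per "
            f"individual; offenders include {bad}"
        )
    d["age_c"] = d["age"] - center_age

    if method == "ols":
        x = sm.add_constant(d["age_c"])
        res = sm.OLS(d["bmi"], x).fit()
        return GrowthModelFit(
            fixed_intercept=float(res.params["const"]),
            fixed_slope=float(res.params["age_c"]),
            random_effects_cov=np.zeros((2, 2)),
            residual_variance=float(res.scale),
            n_individuals=int(obs_per_ind.size),
            n_observations=int(len(d)),
            log_likelihood=float(res.llf),
            converged=True,
            center_age=center_age,
            method="ols",
        )

    model = sm.MixedLM.from_formula(
        "bmi ~ age_c", groups="individual_id", re_formula="~age_c", data=d
    )
    reml = method == "reml"
    # run every optimizer and keep the best-likelihood converged fit: the
    # first-to-converge choice would depend on row order via flaky
    # convergence flags, breaking likelihood invariance to row permutations
    candidates = []

    def attempt(opt):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cand = model.fit(reml=reml, method=opt, maxiter=2000)
            except Exception:  # noqa: BLE001 - try the next optimizer
                return
        if np.isfinite(cand.llf):
            candidates.append(cand)

    for opt in ("lbfgs", "powell"):
        attempt(opt)
    if not any(c.converged for c in candidates):
        attempt("cg")
    converged = [c for c in candidates if c.converged]
    pool = converged or candidates
    if not pool:
        raise RuntimeError("growth model failed to converge with all optimizers")
    res = max(pool, key=lambda c: c.llf)
    if not res.converged:
        raise RuntimeError(
            f"growth model failed to converge; best -2LL {-2 * res.llf:.4f}"
        )

    cov_re = res.cov_re.to_numpy() * res.scale
    b0 = float(res.fe_params["Intercept"])
    b1 = float(res.fe_params["age_c"])
    re = res.random_effects
    blups = pd.DataFrame(
        {
            "individual_id": list(re.keys()),
            "intercept": [b0 + float(v.iloc[0]) for v in re.values()],
            "slope": [b1 + float(v.iloc[1]) for v in re.values()],
        }
    )
    return GrowthModelFit(
        fixed_intercept=b0,
        fixed_slope=b1,
        random_effects_cov=cov_re,
        residual_variance=float(res.scale),
        n_individuals=int(obs_per_ind.size),
        n_observations=int(len(d)),
        log_likelihood=float(res.llf),
        converged=bool(res.converged),
        center_age=center_age,
        method=method,
        blups=blups,
    )


def fit_growth_model(
    long_table: pd.DataFrame,
    center_age: float = 17.5,
    by_sex: bool = True,
    method: str = "reml",
) -> dict[str, GrowthModelFit]:
    """Fit the growth model, by default separately per sex.

    Returns a dict keyed by sex ("M"/"F"), or {"all": fit} when by_sex=False.
    method: "reml" (default), "ml", or "ols" (no random effects; pooled fit).
    """
    if method not in ("reml", "ml", "ols"):
        raise ValueError("method must be 'reml', 'ml' or 'ols'")
    if by_sex:
        out = {}
        for sex, sub in long_table.groupby("sex"):
            out[str(sex)] = _fit_one(sub, center_age, method)
        return out
    return {"all": _fit_one(long_table, center_age, method)}


def extract_individual_trajectories(
    fits: dict[str, GrowthModelFit] | GrowthModelFit,
    long_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-individual (intercept, slope) table from BLUPs of converged fits.

    One row per individual present in the fits; individuals in the table but
    absent from every fit are skipped with a warning.
    """
    if isinstance(fits, GrowthModelFit):
        fits = {"all": fits}
    frames = []
    for _, fit in fits.items():
        if not fit.converged:
            raise ValueError("cannot extract trajectories from a non-converged fit")
        if fit.blups is None:
            raise ValueError("fit has no per-individual random effects (ols method)")
        frames.append(fit.blups)
    est = pd.concat(frames, ignore_index=True)
    meta_cols = [
        c
        for c in ("pair_id", "birth_order", "sex", "zygosity", "opposite_sex")
        if c in long_table.columns
    ]
    meta = long_table[["individual_id"] + meta_cols].drop_duplicates("individual_id")
    skipped = set(meta["individual_id"]) - set(est["individual_id"])
    if skipped:
        logger.warning(
            "%d individuals in the table were absent from the fits and skipped",
            len(skipped),
        )
    out = est.merge(meta, on="individual_id", how="left")
    return out[["individual_id"] + meta_cols + ["intercept", "slope"]]


def per_individual_ols(long_table: pd.DataFrame, center_age: float = 17.5) -> pd.DataFrame:
    """Independent per-individual least-squares lines (no pooling).

    Reference quantity for shrinkage comparisons: BLUP spread never exceeds
    the spread of these unpooled estimates.
    """
    rows = []
    for ind, sub in long_table.dropna(subset=["bmi"]).groupby("individual_id"):
        if len(sub) < 2:
            continue
        x = sub["age"].to_numpy() - center_age
        slope, intercept = np.polyfit(x, sub["bmi"].to_numpy(), 1)
        rows.append({"individual_id": ind, "intercept": intercept, "slope": slope})
    return pd.DataFrame(rows)
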
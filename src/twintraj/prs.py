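"""Polygenic-score residualization, correlation with phenotypes, and KS comparison.

The raw polygenic score is regressed on the top ten genetic principal
components with a family random intercept (population-stratification
correction that respects the twin structure); the conditional (within-family)
residuals are standardized to mean 0 and variance 1 (sample SD, n-1) and used
as the working score.  Correlations with phenotypes are plain Pearson r with
Fisher-z confidence intervals and the conventional weak (< 0.40) / moderate
(0.40-0.59) / strong (>= 0.60) labels.  Distributional representativeness is
assessed with the two-sample Kolmogorov-Smirnov test (exact p for small
samples, asymptotic otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

PC_COLUMNS = [f"PC{i}" for i in range(1, 11)]


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_lower: float
    ci_upper: float
    strength: str


@dataclass
class KsResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def classify_strength(r: float) -> str:
    """|r| in [0, 0.40) weak, [0.40, 0.60) moderate, [0.60, 1] strong."""
    a = abs(r)
    if a >= 0.60:
        return "strong"
    if a >= 0.40:
        return "moderate"
    return "weak"


def residualize_prs(
    prs_table: pd.DataFrame,
    pc_columns=PC_COLUMNS,
    conditional: bool = True,
) -> pd.Series:
    """Standardized PRS residuals after PC regression with a family random effect.

    ``prs_table`` needs columns individual_id, family_id, score (raw scale)
    and the PC columns.  ``conditional=False`` removes only the fixed PC
    effects (marginal residuals), keeping the family deviation in the score.
    Deterministic; returns a Series indexed like the input with mean 0 and
    variance 1 (ddof=1) exactly.
    """
    pc_columns = list(pc_columns)
    missing = [c for c in ["score", "family_id"] + pc_columns if c not in prs_table]
    if missing:
        raise ValueError(f"prs table lacks columns: {missing}")
    n = len(prs_table)
    if n < len(pc_columns) + 10:
        raise ValueError(
            f"need at least {len(pc_columns) + 10} individuals for "
            f"{len(pc_columns)} predictors, got {n}"
        )
    x = prs_table[pc_columns].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("principal components must be finite")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), x]))
    if rank < len(pc_columns) + 1:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        a, b = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"PC design matrix is singular; most collinear pair: "
            f"{pc_columns[a]}, {pc_columns[b]}"
        )

    y = prs_table["score"].to_numpy(dtype=float)
    exog = sm.add_constant(x)
    model = sm.MixedLM(y, exog, groups=prs_table["family_id"].to_numpy())
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    fitted_fixed = exog @ res.fe_params
    resid = y - fitted_fixed
    if conditional:
        re = res.random_effects
        fam_effect = prs_table["family_id"].map(
            {k: float(v.iloc[0]) for k, v in re.items()}
        ).to_numpy()
        resid = resid - fam_effect
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        raise ValueError(
            "residual variance is (numerically) zero: the score is an exact "
            "function of the principal components"
        )
    out = (resid - resid.mean()) / sd
    out = out - out.mean()
    out = out / out.std(ddof=1)
    return pd.Series(out, index=prs_table.index, name="score_residual")


def correlate(
    x: np.ndarray, y: np.ndarray, level: float = 0.95
) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete observation pairs, got {n}")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-15:
        lo = hi = r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        q = stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = float(np.tanh(z - q * se)), float(np.tanh(z + q * se))
    return CorrelationResult(
        r=r, n=n, ci_lower=lo, ci_upper=hi, strength=classify_strength(r)
    )


def correlate_prs(
    residual_scores: pd.Series | pd.DataFrame,
    trait_table: pd.DataFrame,
    traits,
    by_sex: bool = True,
) -> pd.DataFrame:
    """Pearson r between the residualized score and each trait, per sex.

    ``residual_scores``: a DataFrame with columns individual_id and
    score_residual, or a Series indexed by individual_id.  Cells with fewer
    than 3 complete observation pairs are reported with NaN r and a reason.
    """
    if isinstance(residual_scores, pd.Series):
        scores = pd.DataFrame(
            {
                "individual_id": residual_scores.index,
                "score_residual": residual_scores.to_numpy(),
            }
        )
    else:
        scores = residual_scores[["individual_id", "score_residual"]]
    merged = trait_table.merge(scores, on="individual_id", how="inner")
    strata = (
        [(s, g) for s, g in merged.groupby("sex")] if by_sex else [("all", merged)]
    )
    rows = []
    for trait in traits:
        for sex, sub in strata:
            row = {"trait": trait, "sex": sex}
            try:
                res = correlate(
                    sub["score_residual"].to_numpy(), sub[trait].to_numpy()
                )
                row.update(
                    r=res.r, n=res.n, ci_lower=res.ci_lower,
                    ci_upper=res.ci_upper, strength=res.strength, reason="",
                )
            except ValueError as exc:
                row.update(
                    r=np.nan, n=int(sub[trait].notna().sum()), ci_lower=np.nan,
                    ci_upper=np.nan, strength="", reason=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def ks_compare(sample1, sample2, exact_threshold: int = 10_000) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF1 - ECDF2|.

    The exact p-value is used when n1 * n2 <= ``exact_threshold``, the
    asymptotic Kolmogorov distribution otherwise.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    s1 = s1[np.isfinite(s1)]
    s2 = s2[np.isfinite(s2)]
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if len(s1) * len(s2) <= exact_threshold else "asymp"
    res = stats.ks_2samp(s1, s2, method=method)
    return KsResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n1=len(s1), n2=len(s2),
    )
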
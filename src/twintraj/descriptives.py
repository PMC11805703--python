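"""Wave-level descriptives, between-wave BMI change, and twin intraclass correlations.

Includes the published wave-level descriptive statistics of the FinnTwin12 BMI
follow-up (means and SDs of age and BMI per sex and wave, plus the adult
trajectory slope/intercept summaries) as a small reference dataset, so the
between-wave change arithmetic can be demonstrated on the real cohort's
printed values without access to the restricted individual-level data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# Published descriptives of the emulated cohort (566 men, 834 women):
# mean/SD of age and BMI per wave, and the adult-trajectory summaries.
_REFERENCE_WAVE_SUMMARY = """\
measure,wave,sex,n,mean,sd
age,1,M,566,11.42,0.30
age,1,F,834,11.42,0.29
bmi,1,M,566,17.71,2.55
bmi,1,F,834,17.54,2.58
age,2,M,566,14.05,0.08
age,2,F,834,14.04,0.08
bmi,2,M,566,19.34,2.67
bmi,2,F,834,19.35,2.63
age,3,M,566,17.62,0.24
age,3,F,834,17.62,0.27
bmi,3,M,566,21.77,2.94
bmi,3,F,834,20.93,2.72
age,4,M,566,24.18,1.65
age,4,F,834,24.27,1.63
bmi,4,M,566,24.23,3.27
bmi,4,F,834,22.70,3.73
age,5,M,566,37.13,1.45
age,5,F,834,37.21,1.48
bmi,5,M,566,26.16,3.68
bmi,5,F,834,25.02,4.36
slope,,M,566,0.24,0.07
slope,,F,834,0.22,0.12
intercept,,M,566,21.77,2.80
intercept,,F,834,20.99,2.74
"""


def load_reference_wave_summary() -> pd.DataFrame:
    """Published wave-level descriptives of the Finnish twin BMI follow-up."""
    df = pd.read_csv(io.StringIO(_REFERENCE_WAVE_SUMMARY))
    df["wave"] = df["wave"].astype("Int64")
    return df


def wave_summary(
    long_table: pd.DataFrame, trajectories: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per sex-by-wave mean/SD of age and BMI with Welch-t sex-difference p.

    When a trajectories table (individual_id, sex, intercept, slope) is given,
    its columns are summarized the same way (wave left missing).
    """
    if len(long_table) == 0:
        raise ValueError("empty phenotype table")
    rows = []
    for wave, sub in long_table.groupby("wave"):
        by_sex = {s: g for s, g in sub.groupby("sex")}
        for measure in ("age", "bmi"):
            p = np.nan
            if {"M", "F"} <= set(by_sex):
                m = by_sex["M"][measure].dropna()
                f = by_sex["F"][measure].dropna()
                if len(m) > 1 and len(f) > 1:
                    p = float(stats.ttest_ind(m, f, equal_var=False).pvalue)
            for sex, g in sorted(by_sex.items()):
                v = g[measure].dropna()
                if len(v) == 0:
                    continue
                rows.append(
                    {
                        "measure": measure,
                        "wave": wave,
                        "sex": sex,
                        "n": int(len(v)),
                        "mean": float(v.mean()),
                        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                        "p_sex_diff": p,
                    }
                )
    if trajectories is not None:
        for measure in ("intercept", "slope"):
            by_sex = {s: g for s, g in trajectories.groupby("sex")}
            p = np.nan
            if {"M", "F"} <= set(by_sex):
                p = float(
                    stats.ttest_ind(
                        by_sex["M"][measure].dropna(),
                        by_sex["F"][measure].dropna(),
                        equal_var=False,
                    ).pvalue
                )
            for sex, g in sorted(by_sex.items()):
                v = g[measure].dropna()
                rows.append(
                    {
                        "measure": measure,
                        "wave": pd.NA,
                        "sex": sex,
                        "n": int(len(v)),
                        "mean": float(v.mean()),
                        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                        "p_sex_diff": p,
                    }
                )
    out = pd.DataFrame(rows)
    out["wave"] = out["wave"].astype("Int64")
    return out


def bmi_change(
    summary: pd.DataFrame, wave_a: int, wave_b: int, sex: str
) -> tuple[float, float]:
    """Difference of mean BMI between two waves for one sex.

    Returns (rounded to 2 decimals, full precision).  The rounded value
    matches report-table arithmetic on printed means.
    """
    bmi = summary[(summary["measure"] == "bmi") & (summary["sex"] == sex)]
    means = bmi.set_index("wave")["mean"]
    for w in (wave_a, wave_b):
        if w not in means.index:
            raise ValueError(f"wave {w} missing for sex {sex}")
    diff = float(means.loc[wave_b] - means.loc[wave_a])
    return round(diff, 2), diff


@dataclass
class IccResult:
    trait: str
    group: str
    icc: float
    n_pairs: int


def compute_icc(pair_table: pd.DataFrame, trait: str, group: str) -> IccResult:
    """One-way random-effects ANOVA intraclass correlation for twin pairs.

    For pairs of size 2: ICC = (MSB - MSW) / (MSB + MSW) with
    MSB = 2 * sum((pair mean - grand mean)^2) / (n - 1) and
    MSW = sum((x1 - x2)^2 / 2) / n.  Negative estimates are reported as-is.
    """
    wide = pairs_to_wide(pair_table, trait)
    wide = wide.dropna()
    n = len(wide)
    if n < 2:
        raise ValueError(f"group {group}: need >=2 complete pairs, got {n}")
    x1 = wide["twin1"].to_numpy()
    x2 = wide["twin2"].to_numpy()
    pair_mean = (x1 + x2) / 2.0
    grand = pair_mean.mean()  # grand mean of a balanced design
    msb = 2.0 * np.sum((pair_mean - grand) ** 2) / (n - 1)
    msw = np.sum((x1 - x2) ** 2 / 2.0) / n
    if msb + msw == 0:
        raise ValueError(f"group {group}: zero total variance, ICC undefined")
    return IccResult(trait=trait, group=group, icc=float((msb - msw) / (msb + msw)), n_pairs=n)


def pairs_to_wide(pair_table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Long per-individual trait rows -> one row per pair (twin1, twin2).

    Expects columns pair_id, birth_order and the trait column; twins are
    ordered by birth order.
    """
    if {"twin1", "twin2"} <= set(pair_table.columns):
        return pair_table[["twin1", "twin2"]].copy()
    p = pair_table.pivot_table(
        index="pair_id", columns="birth_order", values=trait, aggfunc="first",
        dropna=False,
    )
    p = p.reindex(columns=[1, 2])
    p.columns = ["twin1", "twin2"]
    return p.reset_index(drop=True)


def icc_by_group(traits: pd.DataFrame, trait: str) -> pd.DataFrame:
    """ICC per zygosity-by-sex group (supplementary-table analogue)."""
    from .twin_univariate import assign_group

    t = traits.copy()
    t["group"] = assign_group(t)
    rows = []
    for group, sub in t.groupby("group"):
        try:
            res = compute_icc(sub, trait, str(group))
        except ValueError:
            continue
        rows.append(
            {"trait": trait, "group": group, "icc": res.icc, "n_pairs": res.n_pairs}
        )
    return pd.DataFrame(rows)


def suggest_model(icc_mz: float, icc_dz: float, tolerance: float = 0.05) -> str:
    """Heuristic model hint from the MZ/DZ correlation pattern.

    rDZ < rMZ/2 suggests dominance (ADE-leaning); rDZ > rMZ/2 suggests shared
    environment (ACE-leaning); rDZ ~ rMZ/2 (within the tolerance band) is
    AE-leaning.  Never overrides likelihood-based model comparison.
    """
    half = icc_mz / 2.0
    if abs(icc_dz - half) <= tolerance:
        return "AE-leaning"
    return "ADE-leaning" if icc_dz < half else "ACE-leaning"
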
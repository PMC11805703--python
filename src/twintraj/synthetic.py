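"""Synthetic twin cohorts with known genetic and environmental architecture.

The generator emulates the structure of a longitudinal Finnish twin BMI
follow-up: five zygosity-by-sex groups (MZM, MZF, DZM, DZF, DZOS), five survey
waves at mean ages ~11.5, 14, 17.5, 24 and 37 years, sex-specific trait means,
and an additive-genetic (A) / shared-environment (C) / unique-environment (E)
latent structure.  Additive-genetic latents correlate 1 within MZ pairs and 0.5
within DZ pairs; C latents are identical within a pair; E latents are
independent.  A polygenic score is generated at the score level, loaded on the
first genetic latent factor.

Trait values for k traits are built from lower-triangular loading (path)
matrices T_A, T_C, T_E per sex:

    y = mu_sex + T_A a + T_C c + T_E e,   a, c, e ~ N(0, I_k)

so the implied component covariances are Sigma_X = T_X T_X'.  The DZ genetic
correlation of 0.5 is realized constructively: each DZ co-twin's genetic latent
is sqrt(0.5) * shared + sqrt(0.5) * own, which has exactly the required joint
distribution.

Adult waves (mean age >= the trajectory centering age) are observed from each
individual's latent (intercept, slope) traits as

    bmi(age) = intercept + slope * (age - center) + N(0, obs_residual_sd),

adolescent waves are direct observations of the corresponding bmi trait.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("MZM", "MZF", "DZM", "DZF", "DZOS")
GROUP_ZYGOSITY = {"MZM": "MZ", "MZF": "MZ", "DZM": "DZ", "DZF": "DZ", "DZOS": "DZ"}
GROUP_SEXES = {
    "MZM": ("M", "M"),
    "MZF": ("F", "F"),
    "DZM": ("M", "M"),
    "DZF": ("F", "F"),
    "DZOS": ("M", "F"),
}
SEXES = ("M", "F")

PHENOTYPE_COLUMNS = [
    "individual_id",
    "pair_id",
    "birth_order",
    "sex",
    "zygosity",
    "opposite_sex",
    "wave",
    "age",
    "bmi",
]

_BMI_LABEL = re.compile(r"^bmi(\d+(?:\.\d+)?)$")


def _per_sex(mat, k: int, name: str) -> dict[str, np.ndarray]:
    """Normalize a loading-matrix argument to a {'M': ..., 'F': ...} dict."""
    if mat is None:
        z = np.zeros((k, k))
        return {"M": z, "F": z.copy()}
    if isinstance(mat, dict):
        out = {s: np.asarray(mat[s], dtype=float) for s in SEXES}
    else:
        m = np.asarray(mat, dtype=float)
        out = {"M": m, "F": m.copy()}
    for s, m in out.items():
        if m.shape != (k, k):
            raise ValueError(
                f"{name}[{s}] has shape {m.shape}, expected ({k}, {k}) "
                f"matching the trait labels"
            )
        if not np.allclose(m, np.tril(m)):
            raise ValueError(f"{name}[{s}] must be lower-triangular")
    return out


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic twin cohort.

    Defaults (see :func:`default_config`) reproduce the descriptive scale of
    the emulated cohort: four traits (BMI at 11.5, BMI at 14, adult-trajectory
    intercept and slope), sex-specific means and SDs, AE architecture with
    heritabilities in the 0.6-0.85 range, and 100 pairs per group.
    """

    n_pairs_per_group: dict[str, int]
    trait_labels: tuple[str, ...]
    true_paths_A: dict[str, np.ndarray] | np.ndarray | None = None
    true_paths_C: dict[str, np.ndarray] | np.ndarray | None = None
    true_paths_E: dict[str, np.ndarray] | np.ndarray | None = None
    true_paths_D: None = None  # reserved; dominance generation not implemented
    fixed_means: dict[str, np.ndarray] | np.ndarray | None = None
    wave_ages: list[tuple[float, float]] = field(default_factory=list)
    obs_residual_sd: float = 0.5
    prs_loading: float = 0.35
    missing_rate: float = 0.0
    trajectory_center_age: float = 17.5
    bmi_window: tuple[float, float] = (10.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.trait_labels)
        if k == 0:
            raise ValueError("trait_labels must be non-empty")
        if self.true_paths_D is not None:
            raise NotImplementedError("dominance (D) generation is not implemented")
        self.trait_labels = tuple(self.trait_labels)
        self.true_paths_A = _per_sex(self.true_paths_A, k, "true_paths_A")
        self.true_paths_C = _per_sex(self.true_paths_C, k, "true_paths_C")
        self.true_paths_E = _per_sex(self.true_paths_E, k, "true_paths_E")
        if self.fixed_means is None:
            self.fixed_means = {s: np.zeros(k) for s in SEXES}
        elif not isinstance(self.fixed_means, dict):
            m = np.asarray(self.fixed_means, dtype=float)
            self.fixed_means = {"M": m, "F": m.copy()}
        else:
            self.fixed_means = {
                s: np.asarray(self.fixed_means[s], dtype=float) for s in SEXES
            }
        for s in SEXES:
            if self.fixed_means[s].shape != (k,):
                raise ValueError(f"fixed_means[{s}] must have length {k}")
        self.n_pairs_per_group = {
            g: int(self.n_pairs_per_group.get(g, 0)) for g in GROUPS
        }
        self.validate()

    @property
    def k(self) -> int:
        return len(self.trait_labels)

    def validate(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.prs_loading <= 1.0:
            raise ValueError("prs_loading must be in [0, 1]")
        if any(n < 0 for n in self.n_pairs_per_group.values()):
            raise ValueError("n_pairs_per_group entries must be >= 0")
        for s in SEXES:
            sigma = self.total_covariance(s)
            variances = np.diag(sigma)
            for label, v in zip(self.trait_labels, variances):
                if v <= 0:
                    raise ValueError(
                        f"implied total variance of trait '{label}' ({s}) is "
                        f"non-positive ({v:g}); check the loading matrices"
                    )
            eigvals = np.linalg.eigvalsh(sigma)
            if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
                bad = self.trait_labels[int(np.argmin(np.diag(sigma)))]
                raise ValueError(
                    f"implied phenotypic covariance for sex {s} is not positive "
                    f"semi-definite (min eigenvalue {eigvals.min():.3g}); "
                    f"smallest-variance trait: '{bad}'"
                )

    def component_covariance(self, component: str, sex: str) -> np.ndarray:
        t = {"A": self.true_paths_A, "C": self.true_paths_C, "E": self.true_paths_E}[
            component
        ][sex]
        return t @ t.T

    def total_covariance(self, sex: str) -> np.ndarray:
        return sum(self.component_covariance(x, sex) for x in "ACE")


def _corr_from_cov(sigma: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(sigma))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = sigma / np.outer(d, d)
    r[~np.isfinite(r)] = np.nan
    return r


@dataclass
class SimulationTruth:
    """Implied quantities of a :class:`SimulationConfig` (the truth manifest)."""

    trait_labels: tuple[str, ...]
    shares: dict[str, dict[str, np.ndarray]]      # sex -> component -> a2/c2/e2 per trait
    component_cov: dict[str, dict[str, np.ndarray]]  # sex -> component -> Sigma_X
    component_corr: dict[str, dict[str, np.ndarray]]  # sex -> component -> r_X
    total_cov: dict[str, np.ndarray]
    mz_cross_cov: dict[str, np.ndarray]           # sex -> Sigma_A + Sigma_C
    dz_cross_cov: dict[str, np.ndarray]           # sex -> 0.5 Sigma_A + Sigma_C
    config: SimulationConfig | None = None

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "SimulationTruth":
        shares: dict[str, dict[str, np.ndarray]] = {}
        comp_cov: dict[str, dict[str, np.ndarray]] = {}
        comp_corr: dict[str, dict[str, np.ndarray]] = {}
        total = {}
        mz = {}
        dz = {}
        for s in SEXES:
            covs = {x: config.component_covariance(x, s) for x in "ACE"}
            tot = sum(covs.values())
            v = np.diag(tot)
            shares[s] = {x: np.diag(covs[x]) / v for x in "ACE"}
            comp_cov[s] = covs
            comp_corr[s] = {x: _corr_from_cov(covs[x]) for x in "ACE"}
            total[s] = tot
            mz[s] = covs["A"] + covs["C"]
            dz[s] = 0.5 * covs["A"] + covs["C"]
        return cls(
            trait_labels=config.trait_labels,
            shares=shares,
            component_cov=comp_cov,
            component_corr=comp_corr,
            total_cov=total,
            mz_cross_cov=mz,
            dz_cross_cov=dz,
            config=config,
        )

    def to_json(self) -> str:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            return obj

        payload = {
            "trait_labels": list(self.trait_labels),
            "shares": conv(self.shares),
            "component_cov": conv(self.component_cov),
            "component_corr": conv(self.component_corr),
            "total_cov": conv(self.total_cov),
            "mz_cross_cov": conv(self.mz_cross_cov),
            "dz_cross_cov": conv(self.dz_cross_cov),
        }
        return json.dumps(payload, indent=2)


@dataclass
class SimulatedCohort:
    """Bundle of generator outputs."""

    phenotypes: pd.DataFrame   # long wave-level BMI observations
    traits: pd.DataFrame       # wide per-individual latent trait values
    prs: pd.DataFrame          # individual_id, family_id, score
    pcs: pd.DataFrame          # individual_id, PC1..PC10
    truth: SimulationTruth


def _component_paths(sd: np.ndarray, shares: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Lower-triangular loading matrix with Sigma = D R D, D = diag(sqrt(share)*sd)."""
    d = np.sqrt(np.asarray(shares)) * np.asarray(sd)
    sigma = np.outer(d, d) * np.asarray(corr)
    return np.linalg.cholesky(sigma)


# Default generating conditions: sex-specific trait means/SDs and AE
# architecture on the published descriptive scale of the emulated cohort.
_DEFAULT_LABELS = ("bmi11.5", "bmi14", "intercept", "slope")
_DEFAULT_MEANS = {
    "M": np.array([17.71, 19.34, 21.77, 0.24]),
    "F": np.array([17.54, 19.35, 20.99, 0.22]),
}
_DEFAULT_SDS = {
    "M": np.array([2.55, 2.67, 2.80, 0.07]),
    "F": np.array([2.58, 2.63, 2.74, 0.12]),
}
_DEFAULT_A2 = {
    "M": np.array([0.84, 0.84, 0.81, 0.63]),
    "F": np.array([0.84, 0.84, 0.78, 0.64]),
}


def _corr(b11_b14, b11_int, b11_slp, b14_int, b14_slp, int_slp) -> np.ndarray:
    r = np.eye(4)
    pairs = {
        (0, 1): b11_b14,
        (0, 2): b11_int,
        (0, 3): b11_slp,
        (1, 2): b14_int,
        (1, 3): b14_slp,
        (2, 3): int_slp,
    }
    for (i, j), v in pairs.items():
        r[i, j] = r[j, i] = v
    return r


# Genetic / unique-environment correlation matrices in trait order
# (bmi11.5, bmi14, intercept, slope).  Entries involving the trajectory traits
# follow the emulated cohort's reported component correlations; the
# bmi11.5-bmi14 entries (not reported there) are set to values typical of
# adjacent-age BMI in longitudinal twin data.
_DEFAULT_RA = {
    "M": _corr(0.80, 0.74, 0.42, 0.81, 0.35, 0.50),
    "F": _corr(0.80, 0.74, 0.46, 0.85, 0.66, 0.54),
}
_DEFAULT_RE = {
    "M": _corr(0.40, 0.25, 0.16, 0.29, 0.04, -0.05),
    "F": _corr(0.40, 0.33, 0.09, 0.39, 0.15, 0.07),
}

_DEFAULT_WAVE_AGES = [
    (11.42, 0.30),
    (14.05, 0.08),
    (17.62, 0.25),
    (24.22, 1.64),
    (37.17, 1.47),
]

_DEFAULT_N_PAIRS = {g: 100 for g in GROUPS}


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The four-trait study-analogue generating configuration."""
    paths_a = {}
    paths_e = {}
    for s in SEXES:
        paths_a[s] = _component_paths(_DEFAULT_SDS[s], _DEFAULT_A2[s], _DEFAULT_RA[s])
        paths_e[s] = _component_paths(
            _DEFAULT_SDS[s], 1.0 - _DEFAULT_A2[s], _DEFAULT_RE[s]
        )
    kwargs = dict(
        n_pairs_per_group=dict(_DEFAULT_N_PAIRS),
        trait_labels=_DEFAULT_LABELS,
        true_paths_A=paths_a,
        true_paths_C=None,
        true_paths_E=paths_e,
        fixed_means={s: _DEFAULT_MEANS[s].copy() for s in SEXES},
        wave_ages=list(_DEFAULT_WAVE_AGES),
        obs_residual_sd=0.5,
        prs_loading=0.35,
        missing_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def single_trait_config(
    a2: float,
    c2: float = 0.0,
    *,
    n_pairs: int = 500,
    groups: tuple[str, ...] = ("MZM", "DZM"),
    mean: float = 0.0,
    sd: float = 1.0,
    label: str = "trait",
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """One-trait ACE cohort with standardized shares (a2, c2, 1-a2-c2)."""
    e2 = 1.0 - a2 - c2
    if e2 <= 0:
        raise ValueError("a2 + c2 must be < 1")
    kwargs = dict(
        n_pairs_per_group={g: n_pairs for g in groups},
        trait_labels=(label,),
        true_paths_A=np.array([[np.sqrt(a2) * sd]]),
        true_paths_C=np.array([[np.sqrt(c2) * sd]]),
        true_paths_E=np.array([[np.sqrt(e2) * sd]]),
        fixed_means=np.array([mean]),
        wave_ages=[],
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _wave_plan(config: SimulationConfig) -> list[dict]:
    """Map configured waves to their data source (a bmi trait or the trajectory)."""
    labels = config.trait_labels
    bmi_ages = {}
    for j, lab in enumerate(labels):
        m = _BMI_LABEL.match(lab)
        if m:
            bmi_ages[j] = float(m.group(1))
    has_traj = "intercept" in labels and "slope" in labels
    plan = []
    for w, (mean_age, sd_age) in enumerate(config.wave_ages, start=1):
        source = None
        for j, age in bmi_ages.items():
            if abs(age - mean_age) < 1.0:
                source = ("trait", j)
                break
        if source is None and has_traj and mean_age >= config.trajectory_center_age - 1.0:
            source = (
                "trajectory",
                labels.index("intercept"),
                labels.index("slope"),
            )
        if source is not None:
            plan.append(
                {"wave": w, "mean_age": mean_age, "sd_age": sd_age, "source": source}
            )
    return plan


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a twin cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.k
    truth = SimulationTruth.from_config(config)

    rows = []          # per-individual trait records
    trait_values = []  # per-individual latent trait vectors
    a_first = []       # first genetic latent per individual (for the PRS)
    for group in GROUPS:
        n = config.n_pairs_per_group.get(group, 0)
        if n == 0:
            continue
        zyg = GROUP_ZYGOSITY[group]
        sexes = GROUP_SEXES[group]
        if zyg == "MZ":
            a_shared = rng.standard_normal((n, k))
            a_lat = (a_shared, a_shared)
        else:
            shared = rng.standard_normal((n, k))
            own1 = rng.standard_normal((n, k))
            own2 = rng.standard_normal((n, k))
            r = np.sqrt(0.5)
            a_lat = (r * shared + r * own1, r * shared + r * own2)
        c_shared = rng.standard_normal((n, k))
        e_lat = (rng.standard_normal((n, k)), rng.standard_normal((n, k)))
        for order in (1, 2):
            sex = sexes[order - 1]
            a = a_lat[order - 1]
            e = e_lat[order - 1]
            y = (
                config.fixed_means[sex][None, :]
                + a @ config.true_paths_A[sex].T
                + c_shared @ config.true_paths_C[sex].T
                + e @ config.true_paths_E[sex].T
            )
            for i in range(n):
                pair_id = f"{group}{i:04d}"
                rows.append(
                    {
                        "individual_id": f"{pair_id}_{order}",
                        "pair_id": pair_id,
                        "birth_order": order,
                        "sex": sex,
                        "zygosity": zyg,
                        "opposite_sex": group == "DZOS",
                    }
                )
                trait_values.append(y[i])
                a_first.append(a[i, 0])

    traits = pd.DataFrame(rows)
    if len(traits) == 0:
        raise ValueError("no pairs requested: all n_pairs_per_group are zero")
    tv = np.asarray(trait_values)
    for j, lab in enumerate(config.trait_labels):
        traits[lab] = tv[:, j]
    a_first = np.asarray(a_first)

    # wave-level longitudinal observations
    plan = _wave_plan(config)
    pheno_rows = []
    lo, hi = config.bmi_window
    for entry in plan:
        n_ind = len(traits)
        sd_age = entry["sd_age"]
        if sd_age > 0:
            ages = stats.truncnorm.rvs(
                -3.0, 3.0, loc=entry["mean_age"], scale=sd_age,
                size=n_ind, random_state=rng,
            )
        else:
            ages = np.full(n_ind, entry["mean_age"])
        src = entry["source"]
        if src[0] == "trait":
            bmi = tv[:, src[1]].copy()
        else:
            _, j_int, j_slp = src
            noise = rng.normal(0.0, config.obs_residual_sd, size=n_ind)
            bmi = (
                tv[:, j_int]
                + tv[:, j_slp] * (ages - config.trajectory_center_age)
                + noise
            )
        bmi = np.clip(bmi, lo, hi)
        keep = (
            rng.random(n_ind) >= config.missing_rate
            if config.missing_rate > 0
            else np.ones(n_ind, dtype=bool)
        )
        block = traits[
            ["individual_id", "pair_id", "birth_order", "sex", "zygosity", "opposite_sex"]
        ].copy()
        block["wave"] = entry["wave"]
        block["age"] = ages
        block["bmi"] = bmi
        pheno_rows.append(block[keep])
    if pheno_rows:
        phenotypes = pd.concat(pheno_rows, ignore_index=True)
        phenotypes = phenotypes.sort_values(
            ["pair_id", "birth_order", "wave"], kind="stable"
        ).reset_index(drop=True)
    else:
        phenotypes = pd.DataFrame(columns=PHENOTYPE_COLUMNS)

    # polygenic score on the first genetic latent, standardized
    lam = config.prs_loading
    raw = lam * a_first + np.sqrt(max(0.0, 1.0 - lam**2)) * rng.standard_normal(
        len(a_first)
    )
    score = (raw - raw.mean()) / raw.std(ddof=1)
    prs = pd.DataFrame(
        {
            "individual_id": traits["individual_id"],
            "family_id": traits["pair_id"],
            "score": score,
        }
    )
    pcs = pd.DataFrame(
        rng.standard_normal((len(traits), 10)),
        columns=[f"PC{i}" for i in range(1, 11)],
    )
    pcs.insert(0, "individual_id", traits["individual_id"].to_numpy())

    return SimulatedCohort(
        phenotypes=phenotypes, traits=traits, prs=prs, pcs=pcs, truth=truth
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write the cohort tables (CSV/TSV) and truth manifest JSON to a directory."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out / "phenotypes.csv",
        "traits": out / "traits.csv",
        "prs": out / "prs.tsv",
        "pcs": out / "pcs.tsv",
        "truth": out / "truth.json",
    }
    cohort.phenotypes.to_csv(paths["phenotypes"], index=False)
    cohort.traits.to_csv(paths["traits"], index=False)
    cohort.prs.to_csv(paths["prs"], sep="\t", index=False)
    cohort.pcs.to_csv(paths["pcs"], sep="\t", index=False)
    paths["truth"].write_text(cohort.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
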
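"""End-to-end study analogue: simulate/ingest, trajectories, twin models, PRS.

Stage order: simulate or ingest a cohort -> select individuals complete at the
adult waves -> fit the growth model and extract per-individual trajectories ->
join the four-trait table (adolescent BMIs + intercept + slope) ->
descriptives and intraclass correlations -> univariate twin models per trait
-> multivariate Cholesky per sex -> PRS residualization and correlations.
Every stage writes its table to the output directory and registers it in a
run manifest (row counts, -2LLs, sha256 checksums); no stage mutates an
upstream table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import descriptives, prs as prs_mod, trajectories as traj_mod
from . import twin_multivariate as multi_mod
from . import twin_univariate as uni_mod
from .synthetic import (
    PHENOTYPE_COLUMNS, SimulationConfig, default_config, simulate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

REQUIRED_PHENO_COLUMNS = PHENOTYPE_COLUMNS


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one input mode: ``simulate`` (a SimulationConfig, seed mandatory)
    or ``files`` (paths to phenotype CSV and optional PRS/PC TSVs).
    """

    mode: str = "simulate"
    outdir: str = "twintraj_run"
    seed: int | None = 0
    simulation: SimulationConfig | None = None
    phenotype_path: str | None = None
    prs_path: str | None = None
    pcs_path: str | None = None
    center_age: float = 17.5
    required_waves: tuple[int, ...] = (3, 4, 5)
    trait_labels: tuple[str, ...] = ("bmi11.5", "bmi14", "intercept", "slope")
    univariate_models: tuple[str, ...] = ("ACE", "AE", "E")
    sex_modes: tuple[str, ...] = ("sex_specific", "common", "equal_a")
    run_univariate: bool = True
    run_multivariate: bool = True
    run_prs: bool = True
    ci_level: float = 0.95
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "simulate":
            if self.seed is None:
                raise ValueError("seed is mandatory in simulate mode")
            if self.simulation is None:
                self.simulation = default_config(seed=self.seed)
        elif self.phenotype_path is None:
            raise ValueError("files mode requires phenotype_path")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int | None
    stages: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def record_stage(self, name: str, **info) -> None:
        self.stages[name] = info

    def record_file(self, name: str, path: pathlib.Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path.name)] = digest

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    fields = dataclasses.asdict(config)
    fields.pop("outdir", None)   # where results land does not change them
    fields.pop("log_level", None)
    payload = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()


def _validate_phenotypes(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"phenotype table is missing required columns: {missing}"
        )


def _write(df: pd.DataFrame, path: pathlib.Path, manifest: RunManifest,
           sep: str = ",") -> None:
    df.to_csv(path, index=False, sep=sep, float_format="%.10g")
    manifest.record_file(path.name, path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the run manifest.

    Optional downstream stages that fail are recorded as failed in the
    manifest without discarding completed outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), version=__version__, seed=config.seed
    )

    # --- stage 1: simulate or ingest -------------------------------------
    prs_table = None
    if config.mode == "simulate":
        cohort = simulate_cohort(config.simulation)
        paths = write_cohort(cohort, out / "cohort")
        for p in paths.values():
            manifest.record_file(p, pathlib.Path(p))
        pheno = cohort.phenotypes
        traits_latent = cohort.traits
        if config.run_prs:
            prs_table = cohort.prs.merge(cohort.pcs, on="individual_id")
        manifest.record_stage(
            "input", mode="simulate", n_individuals=int(pheno["individual_id"].nunique()),
            n_rows=int(len(pheno)),
        )
    else:
        pheno = pd.read_csv(config.phenotype_path)
        _validate_phenotypes(pheno)
        traits_latent = None
        if config.run_prs and config.prs_path and config.pcs_path:
            prs_table = pd.read_csv(config.prs_path, sep="\t").merge(
                pd.read_csv(config.pcs_path, sep="\t"), on="individual_id"
            )
        manifest.record_stage(
            "input", mode="files", n_individuals=int(pheno["individual_id"].nunique()),
            n_rows=int(len(pheno)),
        )

    # --- stage 2: completeness filter ------------------------------------
    selected = traj_mod.select_complete_individuals(pheno, config.required_waves)
    manifest.record_stage(
        "select_complete",
        n_individuals=int(selected["individual_id"].nunique()),
        removed=int(pheno["individual_id"].nunique()
                    - selected["individual_id"].nunique()),
    )

    # --- stage 3: growth model + trajectories ----------------------------
    adult = selected[selected["wave"].isin(config.required_waves)]
    fits = traj_mod.fit_growth_model(adult, center_age=config.center_age, by_sex=True)
    traj = traj_mod.extract_individual_trajectories(fits, selected)
    _write(traj, out / "trajectories.csv", manifest)
    manifest.record_stage(
        "trajectories",
        n_individuals=int(len(traj)),
        fits={
            s: {
                "fixed_intercept": f.fixed_intercept,
                "fixed_slope": f.fixed_slope,
                "minus2LL": -2.0 * f.log_likelihood,
                "converged": f.converged,
            }
            for s, f in fits.items()
        },
    )

    # --- stage 4: four-trait join ----------------------------------------
    wave_traits = {}
    for lab in config.trait_labels:
        if lab in ("intercept", "slope"):
            continue
        age = float(lab.replace("bmi", ""))
        wave_means = pheno.groupby("wave")["age"].mean()
        wave = int((wave_means - age).abs().idxmin())
        wt = (
            pheno[pheno["wave"] == wave]
            .dropna(subset=["bmi"])
            .drop_duplicates("individual_id")[["individual_id", "bmi"]]
            .rename(columns={"bmi": lab})
        )
        wave_traits[lab] = wt
    meta = pheno[
        ["individual_id", "pair_id", "birth_order", "sex", "zygosity", "opposite_sex"]
    ].drop_duplicates("individual_id")
    trait_table = meta.merge(
        traj[["individual_id", "intercept", "slope"]], on="individual_id", how="left"
    )
    for lab, wt in wave_traits.items():
        trait_table = trait_table.merge(wt, on="individual_id", how="left")
    trait_table = trait_table[
        list(meta.columns) + [c for c in config.trait_labels]
    ]
    _write(trait_table, out / "traits_joined.csv", manifest)
    manifest.record_stage("trait_join", n_individuals=int(len(trait_table)))

    # --- stage 5: descriptives -------------------------------------------
    summary = descriptives.wave_summary(pheno, trajectories=traj)
    _write(summary, out / "table1_wave_summary.tsv", manifest, sep="\t")
    icc_rows = []
    for lab in config.trait_labels:
        icc_rows.append(descriptives.icc_by_group(trait_table, lab))
    icc = pd.concat(icc_rows, ignore_index=True)
    _write(icc, out / "icc_by_group.tsv", manifest, sep="\t")
    manifest.record_stage("descriptives", n_summary_rows=int(len(summary)))

    # --- stage 6: univariate twin models per trait ------------------------
    if config.run_univariate:
        try:
            uni_rows, cmp_rows = [], []
            for lab in config.trait_labels:
                groups = uni_mod.twin_groups_from_table(trait_table, lab)
                sat = uni_mod.fit_saturated(groups)
                assumption_fit = uni_mod.fit_constrained_saturated(groups)
                fits_u = {}
                for comps in config.univariate_models:
                    for mode in config.sex_modes:
                        if comps == "E" and mode == "equal_a":
                            continue
                        spec = uni_mod.ModelSpec(comps, mode)
                        fits_u[spec.label] = uni_mod.fit_variance_components(
                            groups, spec
                        )
                comparison = uni_mod.compare_models(
                    [assumption_fit] + list(fits_u.values()), sat
                )
                sel_label = comparison.selected
                sel = fits_u.get(sel_label)
                cmp_df = comparison.table.copy()
                cmp_df.insert(0, "trait", lab)
                cmp_rows.append(cmp_df)
                report_fit = sel if sel is not None else fits_u["AE/sex_specific"]
                for sex in ("M", "F"):
                    row = {
                        "trait": lab, "sex": sex, "model": report_fit.label,
                        "selected": report_fit.label == sel_label,
                    }
                    for comp in report_fit.spec.components:
                        share = report_fit.shares[sex][comp]
                        ci = uni_mod.profile_ci(
                            report_fit, (comp, sex), level=config.ci_level
                        )
                        row[f"{comp.lower()}2"] = share
                        row[f"{comp.lower()}2_lo"] = ci.lower
                        row[f"{comp.lower()}2_hi"] = ci.upper
                    uni_rows.append(row)
            uni_df = pd.DataFrame(uni_rows)
            _write(uni_df, out / "table2_variance_components.tsv", manifest, sep="\t")
            cmp_df = pd.concat(cmp_rows, ignore_index=True)
            _write(cmp_df, out / "model_comparison.tsv", manifest, sep="\t")
            manifest.record_stage("twin_univariate", status="ok",
                                  n_traits=len(config.trait_labels))
        except Exception as exc:  # noqa: BLE001 - optional stage isolation
            logger.exception("univariate stage failed")
            manifest.record_stage("twin_univariate", status="failed", error=str(exc))

    # --- stage 7: multivariate Cholesky per sex ----------------------------
    if config.run_multivariate:
        try:
            chol_groups = multi_mod.multitrait_from_table(
                trait_table.dropna(subset=list(config.trait_labels)),
                config.trait_labels,
            )
            chol = multi_mod.fit_cholesky_by_sex(chol_groups)
            rows = []
            labels = config.trait_labels
            for sex, fit in chol.items():
                corr = multi_mod.derive_correlations(fit)
                for i in range(len(labels)):
                    for j in range(i + 1, len(labels)):
                        rows.append(
                            {
                                "sex": sex,
                                "pairing": f"{labels[i]} vs {labels[j]}",
                                "r": corr["r_phenotypic"][i, j],
                                "r_A": corr["r_A"][i, j],
                                "r_E": corr["r_E"][i, j],
                                "minus2LL": fit.minus2LL,
                            }
                        )
            chol_df = pd.DataFrame(rows)
            _write(chol_df, out / "table3_cholesky_correlations.tsv", manifest,
                   sep="\t")
            manifest.record_stage(
                "twin_multivariate", status="ok",
                minus2LL={s: f.minus2LL for s, f in chol.items()},
            )
        except Exception as exc:  # noqa: BLE001
            logger.exception("multivariate stage failed")
            manifest.record_stage("twin_multivariate", status="failed",
                                  error=str(exc))

    # --- stage 8: PRS ------------------------------------------------------
    if config.run_prs and prs_table is not None:
        try:
            resid = prs_mod.residualize_prs(prs_table)
            scores = pd.DataFrame(
                {
                    "individual_id": prs_table["individual_id"],
                    "score_residual": resid.to_numpy(),
                }
            )
            prs_corr = prs_mod.correlate_prs(
                scores, trait_table, config.trait_labels, by_sex=True
            )
            _write(prs_corr, out / "table4_prs_correlations.tsv", manifest, sep="\t")
            manifest.record_stage("prs", status="ok", n_scored=int(len(scores)))
        except Exception as exc:  # noqa: BLE001
            logger.exception("prs stage failed")
            manifest.record_stage("prs", status="failed", error=str(exc))

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
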
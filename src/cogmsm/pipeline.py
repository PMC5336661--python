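"""End-to-end orchestration: read -> impute -> exclude -> score -> classify ->
fit Cox and multi-state models -> report tables.

The pipeline reproduces the standard report layout for a cohort progression
analysis: a cohort-description table, a wave-to-wave transition table, Cox
hazard ratios with concordance, and per-transition multi-state hazard ratios,
plus a provenance JSON recording the seed, stage-by-stage subject counts and
exclusion bookkeeping. Deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .panel import CohortPanel, read_panel, apply_exclusions, DEATH, CENSORED
from .impute import impute_covariates
from .grs import SnpWeightTable, ev_grs_matrix, zscore
from .mci_tb import classify_panel, TESTS
from .msm import MultiStateModel, four_state_structure, three_state_structure
from .cox import CoxAgeScaleModel
from .simulate import empirical_transition_table

log = logging.getLogger("cogmsm.pipeline")


@dataclass
class PipelineConfig:
    """File paths, analysis switches and the seed for one pipeline run."""

    panel_path: str | None = None
    output_dir: str = "cogmsm_output"
    seed: int = 0
    # covariates used in both models (must exist after scoring)
    covariates: tuple[str, ...] = ("adri_score", "grs_z")
    # scoring inputs (optional; covariate columns may already be present)
    snp_weights_path: str | None = None
    genotypes_path: str | None = None
    # MCI definition: "clinical" uses the panel's state column as-is;
    # "mci_tb" reclassifies from psychometric columns (3-state analysis)
    mci_definition: str = "clinical"
    min_tests_impaired: int = 1
    impute_variables: tuple[str, ...] = ()
    complete_case: bool = False
    models: tuple[str, ...] = ("cox", "msm")
    structure: str = "4-state"  # or "3-state"
    interaction: bool = False  # optional product term between the two covariates
    impaired_states: tuple[str, ...] = ("MCI", "DEMENTIA")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for k in ("covariates", "impute_variables", "models", "impaired_states"):
            if k in doc:
                doc[k] = tuple(doc[k])
        return cls(**doc)


def survival_records_from_panel(panel: CohortPanel, covariates,
                                impaired_states=("MCI", "DEMENTIA")) -> pd.DataFrame:
    """Time-to-first-impairment records on the age time scale.

    Entry is the baseline interview age; exit is the age at the first wave
    with an impaired state (event) or the last observation age (censored).
    Subjects already impaired at baseline never contribute a CN->impaired
    conversion and are dropped.
    """
    rows = []
    for sid, grp in panel.data.groupby("subject_id", sort=False):
        ages = grp["age"].to_numpy(dtype=float)
        states = grp["state"].tolist()
        if states[0] in impaired_states:
            continue
        event, exit_age = False, ages[-1]
        for a, s in zip(ages[1:], states[1:]):
            if s in impaired_states:
                event, exit_age = True, a
                break
            exit_age = a
        rec = {"subject_id": sid, "entry_age": ages[0], "exit_age": exit_age,
               "event": event}
        for c in covariates:
            rec[c] = float(grp.iloc[0][c])
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[df["exit_age"] > df["entry_age"]].reset_index(drop=True)


def cohort_description(panel: CohortPanel, covariates) -> pd.DataFrame:
    """Per-wave n, mean age, state counts and baseline covariate summaries."""
    df = panel.data
    rows = []
    for wave, grp in df.groupby("wave"):
        row = {"wave": wave, "n": len(grp), "mean_age": grp["age"].mean()}
        for s in sorted(grp["state"].unique()):
            row[f"n_{s}"] = int((grp["state"] == s).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    base = df.groupby("subject_id", sort=False).first()
    for c in covariates:
        if c in base.columns:
            out.loc[0, f"{c}_mean"] = base[c].mean()
            out.loc[0, f"{c}_sd"] = base[c].std(ddof=1)
    return out


def run_pipeline(config: PipelineConfig, panel: CohortPanel | None = None) -> dict:
    """Run the full analysis; returns the report bundle and writes it to disk.

    ``panel`` may be passed directly (e.g. fresh from the simulator); otherwise
    it is read from ``config.panel_path``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"version": __version__, "seed": config.seed, "stages": []}

    def stage(name, n_in, n_out, **extra):
        log.info("stage %s: %d -> %d subjects %s", name, n_in, n_out, extra or "")
        provenance["stages"].append({"stage": name, "n_in": n_in, "n_out": n_out, **extra})

    if panel is None:
        if config.panel_path is None:
            raise ValueError("either a panel or config.panel_path is required")
        panel = read_panel(config.panel_path)
    stage("read", panel.n_subjects, panel.n_subjects)

    # --- imputation / complete case ------------------------------------
    if config.impute_variables:
        n0 = panel.n_subjects
        if config.complete_case:
            complete = ~panel.data[list(config.impute_variables)].isna().any(axis=1)
            ok_ids = set(panel.data.loc[complete, "subject_id"]) - set(
                panel.data.loc[~complete, "subject_id"])
            panel = CohortPanel(panel.data[panel.data["subject_id"].isin(ok_ids)].copy())
            stage("complete_case", n0, panel.n_subjects,
                  incomplete_excluded=n0 - panel.n_subjects)
        else:
            report = panel.missingness_report(list(config.impute_variables))
            panel = impute_covariates(panel, list(config.impute_variables),
                                      seed=config.seed)
            stage("impute", n0, panel.n_subjects,
                  missingness={r["variable"]: r["fraction"]
                               for _, r in report.table.iterrows()})

    # --- genetic risk score --------------------------------------------
    genotyped = None
    if config.snp_weights_path and config.genotypes_path:
        weights = SnpWeightTable.from_csv(config.snp_weights_path)
        geno = pd.read_csv(config.genotypes_path, index_col=0)
        complete = ~geno.isna().any(axis=1)
        genotyped = set(geno.index[complete])

    # --- exclusions -----------------------------------------------------
    n0 = panel.n_subjects
    panel, counts = apply_exclusions(panel, genotyped)
    stage("exclusions", n0, panel.n_subjects, **counts)
    provenance["exclusions"] = counts

    if config.snp_weights_path and config.genotypes_path:
        raw = ev_grs_matrix(weights, geno.loc[sorted(
            set(panel.subject_ids) & set(geno.index[complete]))])
        z = pd.Series(zscore(raw.to_numpy()), index=raw.index, name="grs_z")
        df = panel.data.merge(z, left_on="subject_id", right_index=True, how="left")
        panel = CohortPanel(df)

    # --- MCI-TB reclassification ---------------------------------------
    label = "clinical"
    if config.mci_definition == "mci_tb":
        label = "mci_tb" if config.min_tests_impaired == 1 else "mci_tb_stringent"
        df = panel.data.copy()
        living = ~df["state"].isin([DEATH, CENSORED])
        needed = ["education_years", *TESTS]
        cls = classify_panel(df.loc[living, ["wave", *needed]],
                             min_tests_impaired=config.min_tests_impaired)
        df.loc[living, "state"] = cls
        panel = CohortPanel(df)

    covs = list(config.covariates)
    if config.interaction:
        base = panel.data.copy()
        base["interaction"] = base[covs[0]] * base[covs[1]]
        panel = CohortPanel(base)
        covs = covs + ["interaction"]

    impaired = (("MCI_TB",) if config.mci_definition == "mci_tb"
                else tuple(config.impaired_states))

    bundle: dict = {"provenance": provenance, "label": label}
    bundle["cohort_description"] = cohort_description(panel, covs)
    bundle["transition_table"] = empirical_transition_table(panel)

    # --- models ---------------------------------------------------------
    if "cox" in config.models:
        recs = survival_records_from_panel(panel, covs, impaired)
        fit = CoxAgeScaleModel(recs, covs).fit()
        hr = fit.hazard_ratios()
        c, c_se = fit.concordance()
        hr["c_index"], hr["c_index_se"] = np.nan, np.nan
        # single-predictor c-indices from univariate refits
        for j, cname in enumerate(covs):
            ufit = CoxAgeScaleModel(recs, [cname]).fit()
            uc, uc_se = ufit.concordance()
            hr.loc[hr["covariate"] == cname, ["c_index", "c_index_se"]] = [uc, uc_se]
        bundle["cox"] = {"fit": fit, "table": hr,
                         "c_index": c, "c_index_se": c_se}

    if "msm" in config.models:
        if config.structure == "3-state" or config.mci_definition == "mci_tb":
            structure = three_state_structure(covs, impaired_state=impaired[0])
        else:
            structure = four_state_structure(covs)
        model = MultiStateModel(panel, structure)
        mfit = model.fit(multistart=0, seed=config.seed)
        bundle["msm"] = {"fit": mfit, "table": mfit.hazard_ratios()}

    _write_bundle(bundle, out_dir, config)
    return bundle


def _write_bundle(bundle: dict, out_dir: Path, config: PipelineConfig) -> None:
    bundle["cohort_description"].to_csv(out_dir / "cohort_description.csv", index=False)
    bundle["transition_table"].to_csv(out_dir / "transition_table.csv")
    if "cox" in bundle:
        t = bundle["cox"]["table"].copy()
        t.to_csv(out_dir / "cox_results.csv", index=False)
    if "msm" in bundle:
        bundle["msm"]["table"].to_csv(out_dir / "msm_results.csv", index=False)
        fit = bundle["msm"]["fit"]
        detail = {
            "label": bundle["label"],
            "theta": {f"{r}->{s}": v for (r, s), v in fit.theta_dict().items()},
            "beta": {f"{r}->{s}": d for (r, s), d in fit.beta_dict().items()},
            "loglik": fit.loglik,
            "converged": fit.converged,
            "covariance": None if fit.cov is None else fit.cov.tolist(),
        }
        (out_dir / "msm_detail.json").write_text(json.dumps(detail, indent=2))
    (out_dir / "provenance.json").write_text(
        json.dumps(bundle["provenance"], indent=2, default=str))
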
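"""Cohort readers/writers, run configuration and the end-to-end pipeline.

The cohort CSV is one row per patient with columns
``patient_id,time,event,<covariates...>``; events are coded 0 censored,
1 relapse, 2 cancer death, 3 other-cause death, and a sidecar JSON data
dictionary maps categorical codes to labels. ``run_pipeline`` chains
simulate/ingest -> landmark -> Cox supermodel -> forest (tuning optional)
-> evaluation -> profiling, writing every artifact plus the resolved
configuration and a log, all reproducible from one seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import check_event_codes
from .cox import fit_cause_specific_cox, landmark_hr_table
from .evaluation import compare_models
from .forest import ForestConfig, fit_forest, minimal_depth, tune_hyperparameters
from .landmark import DEFAULT_GRID, REPORT_GRID, stack_super_dataset
from .profiles import make_profile, plot_profile_curves, profile_cif_curves
from .synthetic import default_cohort_config, generate_cohort

__all__ = ["read_cohort", "write_cohort", "RunConfig", "run_pipeline", "DEFAULT_COX_TERMS"]

log = logging.getLogger("crlandmark")

#: the 20 clinical covariates entering both models by default
DEFAULT_COX_TERMS = (
    "age", "male", "bmi", "charlson", "asa_high", "perioperative_treatment",
    "smoking", "approach", "low_tie", "anastomotic_dehiscence",
    "combined_resection", "operative_time", "transfusion", "conversion",
    "localization", "av_distance", "pT", "pN", "pM", "tnm_stage",
)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Validation: required columns present, strictly positive finite times,
    event codes in {0,1,2,3}, unique patient ids; offending rows are named
    in the error message.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "time", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing required columns: {missing}")
    t = df["time"].to_numpy(dtype=float)
    bad_t = ~(np.isfinite(t) & (t > 0))
    if bad_t.any():
        raise ValueError(f"non-positive or non-finite times on rows {np.flatnonzero(bad_t)[:10].tolist()}")
    check_event_codes(df["event"].to_numpy())
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate patient_id on rows {np.flatnonzero(dup)[:10].tolist()}")
    log.info("read cohort: %d patients, events %s", len(df), df["event"].value_counts().to_dict())
    return df


def write_cohort(df: pd.DataFrame, path, data_dictionary: dict | None = None) -> None:
    """Write the cohort CSV plus a sidecar ``<path>.dict.json`` data dictionary."""
    path = Path(path)
    df.to_csv(path, index=False)
    dictionary = {
        "event": {0: "censored", 1: "relapse", 2: "cancer_death", 3: "other_death"},
        "time": "years from surgery to first event or censoring",
    }
    if data_dictionary:
        dictionary.update(data_dictionary)
    with open(path.with_suffix(path.suffix + ".dict.json"), "w") as fh:
        json.dump({str(k): v for k, v in dictionary.items()}, fh, indent=2, default=str)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    n: int = 2000                       # simulated cohort size (ignored with cohort_csv)
    cohort_csv: str | None = None
    landmark_grid: tuple = DEFAULT_GRID
    horizon: float | None = None
    report_landmarks: tuple = REPORT_GRID
    cox_terms: tuple = DEFAULT_COX_TERMS
    cox_interactions: tuple = ("anastomotic_dehiscence", "combined_resection", "low_tie")
    ntree: int = 100
    mtry: int | None = 5       # OOB-tuned on the default generator
    nodesize: int = 30
    tune: bool = False
    tune_mtry: tuple = (5, 10, 15)
    tune_nodesize: tuple = (5, 15, 30, 50)
    eval_folds: int = 5
    eval_bootstrap: int = 100
    outdir: str = "run_output"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("landmark_grid", "report_landmarks", "cox_terms", "cox_interactions",
                  "tune_mtry", "tune_nodesize"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def validate(self) -> None:
        if len(self.landmark_grid) == 0:
            raise ValueError("landmark grid must be nonempty")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise ValueError(f"cohort file not found: {self.cohort_csv}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Artifacts: cohort.csv, super.csv, cox_hr_table.csv (relapse supermodel,
    report-landmark HRs), minimal_depth.csv, comparison.csv,
    profile_curves.csv/.png, resolved_config.yaml and run.log. Stage
    failures abort with the stage name; earlier outputs are retained.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("crlandmark %s, seed=%d", __version__, config.seed)
    config.to_yaml(out / "resolved_config.yaml")

    stage = "simulate/ingest"
    try:
        if config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
        else:
            cohort = generate_cohort(default_cohort_config(seed=config.seed), config.n)
        write_cohort(cohort, out / "cohort.csv")

        stage = "landmark"
        super_df = stack_super_dataset(cohort, config.landmark_grid, config.horizon)
        super_df.to_csv(out / "super.csv", index=False)
        log.info("super dataset: %d rows over %d landmarks", len(super_df), len(config.landmark_grid))

        stage = "fit-cox"
        fit = fit_cause_specific_cox(
            super_df, 1, [t for t in config.cox_terms if t in super_df.columns],
            [t for t in config.cox_interactions if t in super_df.columns],
        )
        landmark_hr_table(fit, config.report_landmarks).to_csv(out / "cox_hr_table.csv", index=False)

        stage = "fit-forest"
        if config.tune:
            fcfg, tune_table = tune_hyperparameters(
                super_df, config.tune_mtry, config.tune_nodesize,
                ntree=config.ntree, seed=config.seed,
            )
            tune_table.to_csv(out / "tuning.csv", index=False)
        else:
            fcfg = ForestConfig(
                ntree=config.ntree, mtry=config.mtry, nodesize=config.nodesize, seed=config.seed
            )
        forest = fit_forest(super_df, fcfg)
        minimal_depth(forest).to_csv(out / "minimal_depth.csv", index=False)
        log.info("forest OOB error: %s", forest.oob_error)

        stage = "evaluate"
        comparison = compare_models(
            cohort, config.landmark_grid, list(config.cox_terms),
            list(config.cox_interactions), forest_config=fcfg,
            k=config.eval_folds, B=config.eval_bootstrap, seed=config.seed,
            horizon=config.horizon,
        )
        comparison.to_csv(out / "comparison.csv", index=False)

        stage = "profile"
        profiles = {lbl: make_profile(lbl, cohort) for lbl in ("better", "worse")}
        curves = profile_cif_curves(forest, profiles, config.report_landmarks)
        curves.to_csv(out / "profile_curves.csv", index=False)
        plot_profile_curves(curves, out / "profile_curves.png")
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
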
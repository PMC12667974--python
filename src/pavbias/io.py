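"""Tabular dialects, pipeline configuration and stage orchestration.

Trial tables are long-format CSV (subject, session, trial, condition
token gw/ngw/gal/ngal, response go/nogo, outcome -1/0/1, 0-based trial
index).  The pipeline runs simulate/ingest -> QC -> hierarchical fit ->
behavioral stats -> group inference -> quit model, writing one CSV per
report plus a JSON diagnostics file, a config snapshot and a log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .behavior import condition_accuracy, congruency_contrasts
from .cessation import apply_exclusions, credible_group_change, fit_quit_model
from .cohort import CohortData, GenerationConfig, generate_cohort
from .hierarchical import HierarchicalGNG
from .task import CONDITION_TOKENS

__all__ = [
    "read_trials",
    "write_trials",
    "read_cohort",
    "write_cohort",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "REPORT_FILES",
]

logger = logging.getLogger("pavbias")

_TRIAL_COLUMNS = ["subject", "session", "trial", "condition", "response", "outcome"]

#: The six per-stage report files the pipeline emits.
REPORT_FILES = (
    "exclusions.csv",
    "accuracy.csv",
    "contrasts.csv",
    "posterior_summary.csv",
    "group_change.csv",
    "quit_model.csv",
)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a long-format trial table.

    Schema violations raise with the offending (1-based data) row numbers.
    """
    df = pd.read_csv(path)
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def offenders(mask) -> list[int]:
        return (np.flatnonzero(mask.to_numpy()) + 1).tolist()[:10]

    bad = ~df["condition"].isin(CONDITION_TOKENS)
    if bad.any():
        raise ValueError(f"{path}: bad condition token at rows {offenders(bad)}")
    bad = ~df["response"].isin(["go", "nogo"])
    if bad.any():
        raise ValueError(f"{path}: bad response at rows {offenders(bad)}")
    bad = ~df["outcome"].isin([-1, 0, 1])
    if bad.any():
        raise ValueError(f"{path}: outcome outside {{-1,0,1}} at rows {offenders(bad)}")
    bad = ~df["session"].isin([1, 2])
    if bad.any():
        raise ValueError(f"{path}: session outside {{1,2}} at rows {offenders(bad)}")
    dup = df.duplicated(subset=["subject", "session", "trial"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (subject, session, trial) at rows {offenders(dup)}")
    return df[_TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[_TRIAL_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject" not in df.columns:
        raise ValueError(f"{path}: cohort table needs a 'subject' column")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


class SamplerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    chains: int = Field(2, ge=1)
    iterations: int = Field(600, ge=10)
    warmup: int = Field(300, ge=5)
    target_accept: float = 0.9


class PipelineConfig(BaseModel):
    """Everything a pipeline run needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    trials_path: str | None = None     # ingest instead of simulate when set
    cohort_path: str | None = None
    generation: GenerationConfig = GenerationConfig()
    sampler: SamplerSettings = SamplerSettings()
    include_interaction: bool = True
    use_covariates: bool = False       # covariates on the group means
    joint_group_fit: bool = True       # one model with group-specific means
    pi_rew_statistic: str = "mean"     # posterior mean vs median for the quit model
    write_draws: bool = False


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from JSON or YAML."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return PipelineConfig.model_validate(data)


def _fit_groups(trials, groups, covariates, cfg: PipelineConfig, seed_offset=0):
    model = HierarchicalGNG(trials, groups=groups, covariates=covariates)
    s = cfg.sampler
    return model, model.fit(
        chains=s.chains, iterations=s.iterations, warmup=s.warmup,
        seed=cfg.seed + seed_offset, target_accept=s.target_accept,
    )


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages, writing artifacts as each completes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        (out / "config.json").write_text(config.model_dump_json(indent=2))

        # -- stage 1: simulate or ingest --------------------------------
        if config.trials_path:
            trials = read_trials(config.trials_path)
            cohort = read_cohort(config.cohort_path) if config.cohort_path else None
            truth = None
            logger.info("ingested %d trials", len(trials))
        else:
            gen_cfg = config.generation.model_copy(update={"seed": config.seed})
            data: CohortData = generate_cohort(gen_cfg)
            trials, cohort, truth = data.trials, data.cohort, data.truth
            write_trials(trials, out / "trials.csv")
            write_cohort(cohort, out / "cohort.csv")
            truth.to_csv(out / "ground_truth.csv", index=False)
            logger.info("simulated %d subjects, %d trials", len(cohort), len(trials))

        # -- stage 2: QC (pre-fit filters) ------------------------------
        if cohort is not None:
            retained, exclusions = apply_exclusions(cohort, trials)
            exclusions.to_csv(out / "exclusions.csv", index=False)
            logger.info("excluded %d subjects pre-fit", len(exclusions))
            trials = trials[trials["subject"].isin(retained["subject"])]
        else:
            retained = None
            pd.DataFrame(columns=["subject", "reason"]).to_csv(out / "exclusions.csv", index=False)

        # -- stage 3: behavioral statistics -----------------------------
        acc = condition_accuracy(trials)
        acc.to_csv(out / "accuracy.csv", index=False)
        contrasts = congruency_contrasts(acc)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        logger.info("behavioral contrasts:\n%s", contrasts.to_string())

        # -- stage 4: hierarchical fit ----------------------------------
        groups = None
        if retained is not None and config.joint_group_fit and "quit" in retained.columns:
            groups = {
                s: ("quit" if q else "nonquit")
                for s, q in zip(retained["subject"], retained["quit"])
            }
        covariates = None
        if config.use_covariates and retained is not None:
            covariates = retained.set_index("subject")[["KTSND", "CWS", "BIS", "YBOCS"]]
        model, results = _fit_groups(trials, groups, covariates, config)
        diag = results.diagnostics
        results.summary("group").to_csv(out / "posterior_summary.csv")
        (out / "diagnostics.json").write_text(
            json.dumps(
                {
                    "max_rhat": diag.max_rhat,
                    "divergences": diag.divergences,
                    "settings": diag.settings,
                    "n_free_parameters": model.n_free_parameters,
                },
                indent=2,
            )
        )
        if config.write_draws:
            results.posterior.to_dataframe().to_csv(out / "draws.csv", index=False)
        logger.info("fit complete: max R-hat %.3f, %d divergences", diag.max_rhat, diag.divergences)

        # -- stage 5: group-level change --------------------------------
        if groups is not None:
            change = credible_group_change(
                {g: results.group_delta_draws(g) for g in model.group_labels}
            )
        else:
            change = credible_group_change({"all": results.group_delta_draws(None)})
        change.to_csv(out / "group_change.csv", index=False)

        # -- stage 6: quit model ----------------------------------------
        if retained is not None and "quit" in retained.columns:
            nat = results.subject_posterior_mean("natural")
            if config.pi_rew_statistic == "mean":
                pi = nat["pi_rew_s1"]
            else:
                eta = results.eta_draws.reshape(-1, len(model.subjects), 14)
                pi = pd.Series(
                    np.median(eta[:, :, 4], axis=0), index=model.subjects
                )
            quit_res = fit_quit_model(
                retained, pi, include_interaction=config.include_interaction
            )
            quit_res.table.to_csv(out / "quit_model.csv", index=False)
            logger.info("quit model:\n%s", quit_res.table.to_string())
        else:
            pd.DataFrame(columns=["term", "estimate", "se", "z", "p"]).to_csv(
                out / "quit_model.csv", index=False
            )
        logger.info("pipeline complete")
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
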
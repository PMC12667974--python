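"""Synthetic ground-truth cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure the analysis assumes:
subject-level
go/no-go parameters drawn from group normals on the unconstrained scale,
session-2 deltas whose distribution differs by quit group (quitters get a
positive shift on the reward-domain Pavlovian bias by default), behavior
simulated from the RL model on the default task design, covariates,
clinic participation rates, and quit outcomes drawn from a logistic model
with a participation x pi_rew interaction.

Because quit status is both an outcome of the logistic model and the
grouping variable for the session deltas, subjects are drawn candidate by
candidate and kept until each group quota (n_quit / n_nonquit) is full.
This is case-control sampling: logistic slopes remain recoverable (the
intercept absorbs the sampling fraction), and deltas can be drawn
conditionally on the realized group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from .agent import (
    PARAM_NAMES,
    SUBJECT_PARAM_NAMES,
    SubjectParameters,
    natural_values,
    simulate_session,
)
from .task import TaskDesign

__all__ = ["GenerationConfig", "CohortData", "generate_cohort", "recovery_report", "RecoveryReport"]


class QuitCoefficients(BaseModel):
    """Generative logistic coefficients on standardized predictors (log odds)."""

    model_config = ConfigDict(extra="forbid")

    intercept: float = -1.775
    smoking_duration: float = 0.214
    sex_male: float = 0.050
    BIS: float = 0.869
    KTSND: float = -0.109
    CWS: float = -1.073
    YBOCS: float = 0.366
    participation_rate: float = 1.127
    pi_rew: float = -0.067
    interaction: float = -0.845


class GenerationConfig(BaseModel):
    """All knobs of the synthetic cohort, serialized alongside every output."""

    model_config = ConfigDict(extra="forbid")

    n_quit: int = Field(30, ge=1)
    n_nonquit: int = Field(30, ge=1)

    # group-level distribution of the 7 session-1 unconstrained parameters
    # (eps, rho_rew, rho_pun, go_bias, pi_rew, pi_pun, xi): learning rate
    # ~0.31, sensitivities ~3.7, modest go bias, positive Pavlovian biases,
    # lapse ~0.12 -- calibrated so mean condition accuracies fall in the
    # 0.6-0.85 band with congruent > incongruent.
    group_mu: list[float] = [-0.5, 1.3, 1.3, 0.2, 0.6, 0.6, -1.2]
    group_sd: list[float] = [0.5, 0.4, 0.4, 0.5, 0.7, 0.7, 0.3]

    # per-group session-2 delta distributions (unconstrained scale)
    delta_mu_quit: list[float] = [0.0, 0.0, 0.0, 0.0, 0.8, 0.0, 0.0]
    delta_mu_nonquit: list[float] = [0.0] * 7
    delta_sd: list[float] = [0.3] * 7

    quit_coefs: QuitCoefficients = QuitCoefficients()

    participation_alpha: float = 5.0
    participation_beta: float = 1.5
    duration_mean: float = 7.8
    duration_sd: float = 3.5
    p_male: float = 0.86
    survey_days_range: tuple[int, int] = (14, 36)
    co_quit_range: tuple[float, float] = (0.0, 5.0)
    co_nonquit_range: tuple[float, float] = (5.0, 30.0)

    trials_per_condition: int = 45
    p_optimal_correct: float = 0.8
    p_optimal_incorrect: float = 0.2
    simulate_behavior: bool = True

    seed: int = 0
    max_candidate_batches: int = 500

    @model_validator(mode="after")
    def _check_lengths(self):
        for name in ("group_mu", "group_sd", "delta_mu_quit", "delta_mu_nonquit", "delta_sd"):
            if len(getattr(self, name)) != 7:
                raise ValueError(f"{name} must have 7 entries")
        if min(self.group_sd) <= 0 or min(self.delta_sd) <= 0:
            raise ValueError("group SDs must be positive")
        return self

    def design(self) -> TaskDesign:
        return TaskDesign(
            trials_per_condition=self.trials_per_condition,
            p_optimal_correct=self.p_optimal_correct,
            p_optimal_incorrect=self.p_optimal_incorrect,
        )


@dataclass
class CohortData:
    """Generated trial tables, cohort records and per-subject ground truth."""

    trials: pd.DataFrame
    cohort: pd.DataFrame
    truth: pd.DataFrame
    config: GenerationConfig


def _participation_moments(cfg: GenerationConfig) -> tuple[float, float]:
    a, b = cfg.participation_alpha, cfg.participation_beta
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1.0))
    return mean, float(np.sqrt(var))


def generate_cohort(config: GenerationConfig) -> CohortData:
    """Draw a synthetic cohort with known ground truth (bit-reproducible)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_quit + cfg.n_nonquit
    part_mean, part_sd = _participation_moments(cfg)
    coefs = cfg.quit_coefs
    mu = np.asarray(cfg.group_mu)
    sd = np.asarray(cfg.group_sd)

    accepted: list[dict] = []
    quota = {1: cfg.n_quit, 0: cfg.n_nonquit}
    batch = max(4 * n_total, 64)
    for _ in range(cfg.max_candidate_batches):
        if quota[1] == 0 and quota[0] == 0:
            break
        eta1 = mu + sd * rng.standard_normal((batch, 7))
        covs = rng.standard_normal((batch, 4))  # BIS, KTSND, CWS, YBOCS
        duration = np.maximum(cfg.duration_mean + cfg.duration_sd * rng.standard_normal(batch), 0.5)
        sex_male = (rng.random(batch) < cfg.p_male).astype(int)
        participation = rng.beta(cfg.participation_alpha, cfg.participation_beta, batch)
        z_part = (participation - part_mean) / part_sd
        z_pi = (eta1[:, 4] - mu[4]) / sd[4]
        z_dur = (duration - cfg.duration_mean) / cfg.duration_sd
        lp = (
            coefs.intercept
            + coefs.smoking_duration * z_dur
            + coefs.sex_male * sex_male
            + coefs.BIS * covs[:, 0]
            + coefs.KTSND * covs[:, 1]
            + coefs.CWS * covs[:, 2]
            + coefs.YBOCS * covs[:, 3]
            + coefs.participation_rate * z_part
            + coefs.pi_rew * z_pi
            + coefs.interaction * z_part * z_pi
        )
        p_quit = expit(lp)
        quit = (rng.random(batch) < p_quit).astype(int)
        for j in range(batch):
            q = int(quit[j])
            if quota[q] == 0:
                continue
            quota[q] -= 1
            accepted.append(
                dict(
                    eta1=eta1[j], BIS=covs[j, 0], KTSND=covs[j, 1], CWS=covs[j, 2],
                    YBOCS=covs[j, 3], smoking_duration=duration[j], sex_male=sex_male[j],
                    participation_rate=participation[j], lp=lp[j], p_quit=p_quit[j], quit=q,
                )
            )
            if quota[1] == 0 and quota[0] == 0:
                break
    if quota[1] or quota[0]:
        raise ValueError(
            "could not fill group quotas; check quit-model coefficients/intercept"
        )

    design = cfg.design()
    trial_frames = []
    cohort_rows = []
    truth_rows = []
    width = len(str(n_total))
    for idx, rec in enumerate(accepted):
        subj = f"s{idx + 1:0{width}d}"
        group = "quit" if rec["quit"] else "nonquit"
        dmu = np.asarray(cfg.delta_mu_quit if rec["quit"] else cfg.delta_mu_nonquit)
        delta = dmu + np.asarray(cfg.delta_sd) * rng.standard_normal(7)
        params = SubjectParameters(eta1=rec["eta1"], delta=delta)

        if cfg.simulate_behavior:
            for sess, p_sess in ((1, params.session1()), (2, params.session2())):
                records = simulate_session(p_sess, design, rng, subject=subj, session=sess)
                trial_frames.append(
                    pd.DataFrame(
                        {
                            "subject": subj,
                            "session": sess,
                            "trial": [t.trial for t in records],
                            "condition": [t.condition.token for t in records],
                            "response": ["go" if t.response else "nogo" for t in records],
                            "outcome": [t.outcome for t in records],
                        }
                    )
                )

        co_lo, co_hi = cfg.co_quit_range if rec["quit"] else cfg.co_nonquit_range
        cohort_rows.append(
            dict(
                subject=subj,
                sex_male=rec["sex_male"],
                smoking_duration=rec["smoking_duration"],
                BIS=rec["BIS"], KTSND=rec["KTSND"], CWS=rec["CWS"], YBOCS=rec["YBOCS"],
                participation_rate=rec["participation_rate"],
                survey_days=int(rng.integers(cfg.survey_days_range[0], cfg.survey_days_range[1] + 1)),
                co_ppm=float(rng.uniform(co_lo, co_hi)),
                smoked_last_week=not rec["quit"],
                quit=rec["quit"],
                flag_data_issue=False,
                flag_low_concentration=False,
            )
        )
        nat1 = natural_values(rec["eta1"])
        nat2 = natural_values(rec["eta1"] + delta)
        row = dict(subject=subj, group=group, lp=rec["lp"], p_quit=rec["p_quit"], quit=rec["quit"])
        row.update({n: v for n, v in zip(SUBJECT_PARAM_NAMES, np.concatenate([rec["eta1"], delta]))})
        row.update({f"{n}_nat_s1": v for n, v in zip(PARAM_NAMES, nat1)})
        row.update({f"{n}_nat_s2": v for n, v in zip(PARAM_NAMES, nat2)})
        truth_rows.append(row)

    trials = (
        pd.concat(trial_frames, ignore_index=True)
        if trial_frames
        else pd.DataFrame(columns=["subject", "session", "trial", "condition", "response", "outcome"])
    )
    return CohortData(
        trials=trials,
        cohort=pd.DataFrame(cohort_rows),
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


@dataclass
class RecoveryReport:
    """Parameter-recovery metrics from a fit on generated data."""

    parameters: pd.DataFrame    # per parameter: correlation, bias, rmse, coverage95
    group_deltas: pd.DataFrame  # per group x delta: truth mean, posterior median, sign flags

    def correlation(self, parameter: str) -> float:
        return float(self.parameters.loc[parameter, "correlation"])


def recovery_report(data: CohortData, results) -> RecoveryReport:
    """Compare generating subject parameters with the fitted posterior.

    Correlation, bias, RMSE and 95%-interval coverage per unconstrained
    parameter, plus group-level delta medians with sign-recovery flags.
    """
    truth = data.truth.set_index("subject")
    fitted_subjects = list(results.model.subjects)
    missing = set(fitted_subjects) - set(truth.index)
    if missing:
        raise ValueError(f"fitted subjects missing from ground truth: {sorted(missing)}")
    truth = truth.loc[fitted_subjects]
    post_mean = results.subject_posterior_mean()

    rows = []
    for pname in SUBJECT_PARAM_NAMES:
        t = truth[pname].to_numpy(dtype=float)
        m = post_mean[pname].to_numpy()
        lohi = results.subject_hdi(pname, 0.95)
        rows.append(
            {
                "parameter": pname,
                "correlation": float(np.corrcoef(t, m)[0, 1]),
                "bias": float(np.mean(m - t)),
                "rmse": float(np.sqrt(np.mean((m - t) ** 2))),
                "coverage95": float(np.mean((lohi["lo"].to_numpy() <= t) & (t <= lohi["hi"].to_numpy()))),
            }
        )
    params = pd.DataFrame(rows).set_index("parameter")

    cfg = data.config
    delta_truth = {"quit": cfg.delta_mu_quit, "nonquit": cfg.delta_mu_nonquit}
    grows = []
    for group in results.model.group_labels:
        draws = results.group_delta_draws(group)
        tmu = delta_truth.get(str(group), [np.nan] * 7)
        for k, (dname, d) in enumerate(draws.items()):
            med = float(np.median(d))
            grows.append(
                {
                    "group": group,
                    "parameter": dname,
                    "truth_mean": tmu[k],
                    "posterior_median": med,
                    "sign_recovered": bool(np.sign(med) == np.sign(tmu[k])) if tmu[k] else bool(abs(med) < 0.5),
                }
            )
    return RecoveryReport(parameters=params, group_deltas=pd.DataFrame(grows))
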
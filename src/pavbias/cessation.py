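"""Cohort QC, abstinence classification, and the cessation moderation model.

The moderation analysis asks whether Pavlovian bias in the reward domain
(pi_rew) dampens the benefit of clinic participation: a logistic
regression of quit success on standardized covariates, participation
rate, pi_rew, and their interaction.  Group-level session deltas from the
hierarchical fit are assessed for credible change via 95% HDIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .hierarchical import hdi

__all__ = [
    "CO_ABSTINENCE_PPM",
    "EXCLUSION_REASONS",
    "classify_abstinence",
    "apply_exclusions",
    "QuitModel",
    "QuitModelResults",
    "fit_quit_model",
    "moderation_profile",
    "credible_group_change",
]

#: Exhaled CO must be strictly below this (ppm) to corroborate abstinence.
CO_ABSTINENCE_PPM = 5.0

#: Exclusion reason codes in priority order (first matching wins).
EXCLUSION_REASONS = (
    "data_issue",
    "low_concentration",
    "excessive_presses",
    "model_convergence",
    "incomplete_survey",
)

_COVARIATES = ["smoking_duration", "BIS", "KTSND", "CWS", "YBOCS"]
_TERM_LABELS = {
    "const": "(Intercept)",
    "smoking_duration": "Smoking duration",
    "sex_male": "Sex: male",
    "BIS": "BIS",
    "KTSND": "KTSND",
    "CWS": "CWS",
    "YBOCS": "YBOCS",
    "participation_rate": "Participation rate",
    "pi_rew": "pi_rew",
    "participation_x_pi_rew": "Participation rate x pi_rew",
}


def classify_abstinence(co_ppm: float, smoked_last_week: bool) -> bool:
    """CO-verified abstinence: CO strictly below 5 ppm and no reported smoking."""
    if co_ppm < 0:
        raise ValueError(f"CO concentration cannot be negative, got {co_ppm}")
    return (co_ppm < CO_ABSTINENCE_PPM) and not smoked_last_week


def _go_rate_by_session(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials.copy()
    t["is_go"] = t["response"] == "go"
    return t.groupby(["subject", "session"])["is_go"].mean().unstack("session")


def apply_exclusions(
    cohort: pd.DataFrame,
    trials: pd.DataFrame | None = None,
    max_rhat_by_subject: dict | pd.Series | None = None,
    go_rate_threshold: float = 0.9,
    rhat_threshold: float = 1.1,
    min_survey_days: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the QC / exclusion filters; returns (retained cohort, exclusion log).

    Reasons, first match wins, in order: raised data-issue flag, raised
    low-concentration flag, go responses on > 90% of a session's trials,
    any parameter R-hat above 1.1, fewer than 7 smoking-survey days.  The
    log has one (subject, reason) row per excluded subject.
    """
    cohort = cohort.set_index("subject", drop=False) if "subject" in cohort.columns else cohort
    if trials is not None:
        extra = set(trials["subject"].unique()) - set(cohort.index)
        if extra:
            raise ValueError(f"subjects in trials but not in cohort: {sorted(map(str, extra))}")
        go_rates = _go_rate_by_session(trials)
    else:
        go_rates = None
    if max_rhat_by_subject is not None and not isinstance(max_rhat_by_subject, pd.Series):
        max_rhat_by_subject = pd.Series(max_rhat_by_subject)

    reasons: dict = {}
    for subj, row in cohort.iterrows():
        if bool(row.get("flag_data_issue", False)):
            reasons[subj] = "data_issue"
        elif bool(row.get("flag_low_concentration", False)):
            reasons[subj] = "low_concentration"
        elif go_rates is not None and subj in go_rates.index and (
            np.nanmax(go_rates.loc[subj].to_numpy(dtype=float)) > go_rate_threshold
        ):
            reasons[subj] = "excessive_presses"
        elif max_rhat_by_subject is not None and subj in max_rhat_by_subject.index and (
            max_rhat_by_subject[subj] > rhat_threshold
        ):
            reasons[subj] = "model_convergence"
        elif "survey_days" in cohort.columns and row["survey_days"] < min_survey_days:
            reasons[subj] = "incomplete_survey"
    log = pd.DataFrame(
        {"subject": list(reasons), "reason": list(reasons.values())}
    )
    retained = cohort.drop(index=list(reasons)).reset_index(drop=True)
    return retained, log


class QuitModel:
    """Logistic regression of cessation success (statsmodels-style model).

    Terms: intercept, smoking duration, sex (male indicator), BIS, KTSND,
    CWS, YBOCS, clinic participation rate, session-1 pi_rew, and
    optionally participation x pi_rew.  Continuous predictors are
    z-scored before entry; the interaction is the product of the
    standardized components.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        pi_rew: pd.Series | np.ndarray | None = None,
        include_interaction: bool = True,
        min_subjects: int = 20,
    ):
        df = cohort.reset_index(drop=True).copy()
        if pi_rew is not None:
            if isinstance(pi_rew, pd.Series):
                df["pi_rew"] = pi_rew.loc[df["subject"]].to_numpy()
            else:
                df["pi_rew"] = np.asarray(pi_rew, dtype=float)
        if "pi_rew" not in df.columns:
            raise ValueError("pi_rew estimates are required (column or argument)")
        if len(df) < min_subjects:
            raise ValueError(f"need at least {min_subjects} retained subjects, got {len(df)}")
        y = df["quit"].astype(int).to_numpy()
        if y.min() == y.max():
            raise ValueError("both outcome classes must be present")

        def zscore(col):
            v = df[col].astype(float).to_numpy()
            sd = v.std(ddof=0)
            if sd == 0:
                raise ValueError(f"constant predictor {col!r}")
            return (v - v.mean()) / sd

        design = pd.DataFrame(
            {
                "const": np.ones(len(df)),
                "smoking_duration": zscore("smoking_duration"),
                "sex_male": df["sex_male"].astype(float).to_numpy(),
                "BIS": zscore("BIS"),
                "KTSND": zscore("KTSND"),
                "CWS": zscore("CWS"),
                "YBOCS": zscore("YBOCS"),
                "participation_rate": zscore("participation_rate"),
                "pi_rew": zscore("pi_rew"),
            }
        )
        if include_interaction:
            design["participation_x_pi_rew"] = (
                design["participation_rate"] * design["pi_rew"]
            )
        self.include_interaction = include_interaction
        self.endog = y
        self.exog = design
        self._sm = sm.Logit(y, design)

    def fit(self) -> "QuitModelResults":
        """Maximum-likelihood fit with Wald standard errors."""
        if np.linalg.matrix_rank(self.exog.to_numpy()) < self.exog.shape[1]:
            raise ValueError("singular design matrix")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = self._sm.fit(disp=False, maxiter=200)
            except np.linalg.LinAlgError:
                # near-separated likelihoods can make the Hessian numerically
                # singular at the Newton optimum; retry with BFGS and flag
                warnings.simplefilter("always")
                res = self._sm.fit(disp=False, maxiter=500, method="bfgs")
                warnings.warn(
                    "quit model Hessian numerically singular (possible quasi-"
                    "separation); BFGS estimates returned", stacklevel=2,
                )
        for w in caught:
            if "separat" in str(w.message).lower():
                warnings.warn(
                    f"possible quasi-separation in quit model: {w.message}", stacklevel=2
                )
        return QuitModelResults(self, res)


class QuitModelResults:
    """Coefficient table (Wald z tests), covariance, and simple-slope profiles."""

    def __init__(self, model: QuitModel, sm_results):
        self.model = model
        self._res = sm_results
        self.converged = bool(sm_results.mle_retvals.get("converged", True))

    @property
    def table(self) -> pd.DataFrame:
        """Term, estimate, SE, z, p — mirroring the published table layout."""
        out = pd.DataFrame(
            {
                "term": [_TERM_LABELS.get(c, c) for c in self.model.exog.columns],
                "estimate": self._res.params.to_numpy(),
                "se": self._res.bse.to_numpy(),
                "z": self._res.tvalues.to_numpy(),
                "p": self._res.pvalues.to_numpy(),
            }
        )
        return out

    def params(self) -> pd.Series:
        return self._res.params

    def cov_params(self) -> pd.DataFrame:
        return self._res.cov_params()

    def summary(self):
        return self._res.summary()

    def moderation_profile(self, pi_grid: np.ndarray) -> pd.DataFrame:
        """Simple slope of participation at standardized pi_rew values.

        slope(pi) = beta_participation + beta_interaction * pi, with the
        delta-method SE from the Wald covariance.
        """
        if not self.model.include_interaction:
            raise ValueError("model was fit without the interaction term")
        pi_grid = np.asarray(pi_grid, dtype=float)
        b = self._res.params
        v = self._res.cov_params()
        bp, bi = b["participation_rate"], b["participation_x_pi_rew"]
        vpp = v.loc["participation_rate", "participation_rate"]
        vii = v.loc["participation_x_pi_rew", "participation_x_pi_rew"]
        vpi = v.loc["participation_rate", "participation_x_pi_rew"]
        slope = bp + bi * pi_grid
        se = np.sqrt(vpp + pi_grid**2 * vii + 2.0 * pi_grid * vpi)
        return pd.DataFrame({"pi_rew": pi_grid, "slope": slope, "se": se})

    def plot_moderation(self, pi_grid: np.ndarray | None = None, ax=None):
        """Participation simple slopes across pi_rew with +-1 SE band."""
        import matplotlib.pyplot as plt

        if pi_grid is None:
            pi_grid = np.linspace(-2, 2, 41)
        prof = self.moderation_profile(pi_grid)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(prof["pi_rew"], prof["slope"], color="C0")
        ax.fill_between(
            prof["pi_rew"], prof["slope"] - prof["se"], prof["slope"] + prof["se"],
            alpha=0.3, color="C0",
        )
        ax.axhline(0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("Pavlovian bias (reward), standardized")
        ax.set_ylabel("effect of participation rate (log odds)")
        return ax


def fit_quit_model(
    cohort: pd.DataFrame,
    pi_rew: pd.Series | np.ndarray | None = None,
    include_interaction: bool = True,
) -> QuitModelResults:
    """Convenience wrapper: build and fit the quit logistic model."""
    return QuitModel(cohort, pi_rew, include_interaction=include_interaction).fit()


def moderation_profile(results: QuitModelResults, pi_grid: np.ndarray) -> pd.DataFrame:
    """Functional alias for :meth:`QuitModelResults.moderation_profile`."""
    return results.moderation_profile(pi_grid)


def credible_group_change(
    delta_draws_by_group: dict, mass: float = 0.95
) -> pd.DataFrame:
    """Assess group-level session deltas for credible change.

    ``delta_draws_by_group`` maps group label -> {parameter -> flat
    draws}.  A change is credible when the 95% HDI excludes zero; the
    direction column reports the sign of the posterior median.
    """
    rows = []
    for group, per_param in delta_draws_by_group.items():
        for pname, draws in per_param.items():
            lo, hi = hdi(draws, mass)
            med = float(np.median(draws))
            rows.append(
                {
                    "group": group,
                    "parameter": pname,
                    "median": med,
                    "hdi_lo": lo,
                    "hdi_hi": hi,
                    "credible": bool(lo > 0 or hi < 0),
                    "direction": "increase" if med > 0 else "decrease",
                }
            )
    return pd.DataFrame(rows)
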
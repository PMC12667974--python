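"""Condition accuracies, congruency contrasts and effect sizes.

The behavioral signature of Pavlovian bias is better accuracy in
congruent conditions (go-to-win, no-go-to-avoid) than incongruent ones
(no-go-to-win, go-to-avoid).  Accuracy is the fraction of trials whose
response matches the condition's required action; contrasts are paired t
tests across subjects with a pooled-SD Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import CONDITION_TOKENS

__all__ = [
    "condition_accuracy",
    "paired_t",
    "cohens_d_pooled",
    "congruency_contrasts",
    "CONTRASTS",
]

_GO_CORRECT = {"gw": "go", "ngw": "nogo", "gal": "go", "ngal": "nogo"}

#: (name, favored condition, other condition); favored is the congruent one.
CONTRASTS = (
    ("go_win_vs_nogo_win", "gw", "ngw"),
    ("nogo_avoid_vs_go_avoid", "ngal", "gal"),
)


def condition_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x session x condition fraction of correct responses.

    Conditions with zero trials for a subject-session yield NaN accuracy
    and are flagged in the ``n_trials`` column.
    """
    df = trials.copy()
    bad = ~df["condition"].isin(CONDITION_TOKENS)
    if bad.any():
        raise ValueError(f"unknown condition tokens: {sorted(df.loc[bad, 'condition'].unique())}")
    df["correct"] = df["response"] == df["condition"].map(_GO_CORRECT)
    grouped = (
        df.groupby(["subject", "session", "condition"], sort=False)["correct"]
        .agg(accuracy="mean", n_trials="size")
        .reset_index()
    )
    # complete the grid so absent conditions appear as flagged NaN rows
    pairs = grouped[["subject", "session"]].drop_duplicates()
    grid = pd.MultiIndex.from_frame(
        pairs.merge(pd.Series(CONDITION_TOKENS, name="condition"), how="cross")
    )
    full = (
        grouped.set_index(["subject", "session", "condition"])
        .reindex(grid)
        .reset_index()
    )
    full["n_trials"] = full["n_trials"].fillna(0).astype(int)
    return full


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Paired t test on differences x - y: returns (t, df, two-sided p).

    Zero-variance differences have no defined t; (nan, df, nan) is
    returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("paired_t needs two equal-length 1-d arrays, n >= 3")
    d = x - y
    df = x.size - 1
    if np.std(d, ddof=1) == 0.0:
        warnings.warn("zero-variance differences: t undefined", stacklevel=2)
        return float("nan"), df, float("nan")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), df, float(res.pvalue)


def cohens_d_pooled(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d with the average-variance pooled SD: (m1-m2)/sqrt((s1^2+s2^2)/2)."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        warnings.warn("both SDs zero: d undefined", stacklevel=2)
        return float("nan")
    return (m1 - m2) / np.sqrt((s1**2 + s2**2) / 2.0)


def congruency_contrasts(
    accuracy: pd.DataFrame, session: int | None = None
) -> pd.DataFrame:
    """Congruent-vs-incongruent accuracy contrasts per session.

    Two contrasts each session: go-win vs no-go-win and no-go-avoid vs
    go-avoid, reported with means, SDs, paired t, df, p and pooled-SD d.
    """
    sessions = [session] if session is not None else sorted(accuracy["session"].unique())
    wide = accuracy.pivot_table(
        index=["subject", "session"], columns="condition", values="accuracy"
    )
    rows = []
    for sess in sessions:
        try:
            block = wide.xs(sess, level="session")
        except KeyError:
            raise ValueError(f"no accuracy rows for session {sess}")
        for name, cond1, cond2 in CONTRASTS:
            for cond in (cond1, cond2):
                if cond not in block.columns or block[cond].isna().all():
                    raise ValueError(f"condition {cond!r} missing in session {sess}")
            pair = block[[cond1, cond2]].dropna()
            x, y = pair[cond1].to_numpy(), pair[cond2].to_numpy()
            t, df, p = paired_t(x, y)
            rows.append(
                {
                    "session": sess,
                    "contrast": name,
                    "mean1": x.mean(),
                    "sd1": x.std(ddof=1),
                    "mean2": y.mean(),
                    "sd2": y.std(ddof=1),
                    "t": t,
                    "df": df,
                    "p": p,
                    "d": cohens_d_pooled(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)
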
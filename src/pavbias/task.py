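"""Orthogonalized go/no-go task design and outcome schedule.

The task crosses required action (go / no-go) with cue valence (win /
avoid), giving four cue conditions.  Win cues pay +1 (reward) or 0; avoid
cues pay 0 or -1 (punishment).  Feedback is probabilistic: the optimal
outcome follows a correct response with probability ``p_optimal_correct``
(default 0.8) and an incorrect response with probability
``p_optimal_incorrect`` (default 0.2).  A session has 45 trials per
condition, 180 in total, in a uniformly shuffled order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Action",
    "Valence",
    "CueCondition",
    "CONDITIONS",
    "CONDITION_TOKENS",
    "TaskDesign",
    "TrialRecord",
    "correct_action",
    "generate_trial_sequence",
    "sample_outcome",
]


class Action(enum.IntEnum):
    NOGO = 0
    GO = 1


class Valence(enum.IntEnum):
    AVOID = 0
    WIN = 1


@dataclass(frozen=True)
class CueCondition:
    """One of the four cue types: an action requirement crossed with a valence."""

    action_requirement: Action
    valence: Valence

    @property
    def token(self) -> str:
        return CONDITION_TOKENS[CONDITIONS.index(self)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CueCondition({self.token})"


#: Canonical condition order: go-win, nogo-win, go-avoid, nogo-avoid.
CONDITIONS: tuple[CueCondition, ...] = (
    CueCondition(Action.GO, Valence.WIN),
    CueCondition(Action.NOGO, Valence.WIN),
    CueCondition(Action.GO, Valence.AVOID),
    CueCondition(Action.NOGO, Valence.AVOID),
)

#: CSV tokens, same order: go-win, nogo-win, go-avoid ("go to avoid losing"),
#: nogo-avoid.
CONDITION_TOKENS: tuple[str, ...] = ("gw", "ngw", "gal", "ngal")

_TOKEN_TO_INDEX = {t: i for i, t in enumerate(CONDITION_TOKENS)}


def condition_from_token(token: str) -> CueCondition:
    try:
        return CONDITIONS[_TOKEN_TO_INDEX[token]]
    except KeyError:
        raise ValueError(f"unknown condition token {token!r}; expected one of {CONDITION_TOKENS}")


def condition_index(condition: CueCondition) -> int:
    """Index of a condition in the canonical order (0..3)."""
    try:
        return CONDITIONS.index(condition)
    except ValueError:
        raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class TaskDesign:
    """Trial counts and the probabilistic outcome contingencies.

    The optimal-outcome probability after a correct response mirrors the
    20% incorrect-response contingency at 80%; both are explicit fields so
    an asymmetric schedule can be configured.
    """

    trials_per_condition: int = 45
    p_optimal_correct: float = 0.8
    p_optimal_incorrect: float = 0.2

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if not 0.0 <= self.p_optimal_incorrect <= self.p_optimal_correct <= 1.0:
            raise ValueError(
                "require 0 <= p_optimal_incorrect <= p_optimal_correct <= 1, got "
                f"({self.p_optimal_incorrect}, {self.p_optimal_correct})"
            )

    @property
    def n_trials(self) -> int:
        return 4 * self.trials_per_condition


@dataclass(frozen=True)
class TrialRecord:
    """One task trial: cue, emitted response, and delivered outcome."""

    subject: str
    session: int
    trial: int
    condition: CueCondition
    response: Action
    outcome: int

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session}")
        admissible = (1, 0) if self.condition.valence == Valence.WIN else (0, -1)
        if self.outcome not in admissible:
            raise ValueError(
                f"outcome {self.outcome} not admissible for {self.condition.token} "
                f"(valence allows {admissible})"
            )


def correct_action(condition: CueCondition) -> Action:
    """The instrumentally required response for a cue condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    return condition.action_requirement


def generate_trial_sequence(
    design: TaskDesign = TaskDesign(), seed: int | np.random.Generator = 0
) -> list[CueCondition]:
    """Seeded uniform permutation with exactly ``trials_per_condition`` of each cue."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.repeat(np.arange(4), design.trials_per_condition)
    rng.shuffle(idx)
    return [CONDITIONS[i] for i in idx]


def sample_outcome(
    condition: CueCondition,
    response: Action,
    u: float,
    design: TaskDesign = TaskDesign(),
) -> int:
    """Map a uniform deviate to the delivered outcome.

    ``u < p`` selects the optimal outcome, where p depends on whether the
    response matches the condition's required action.  Win cues deliver
    +1 (optimal) or 0; avoid cues deliver 0 (optimal) or -1.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError(f"u must lie in [0, 1), got {u}")
    p = design.p_optimal_correct if response == correct_action(condition) else design.p_optimal_incorrect
    optimal = u < p
    if condition.valence == Valence.WIN:
        return 1 if optimal else 0
    return 0 if optimal else -1
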
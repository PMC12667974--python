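"""Reinforcement-learning agent for the orthogonalized go/no-go task.

The model is a Rescorla–Wagner learner with separate reward and punishment
sensitivities, a constant go bias, valence-specific Pavlovian biases that
couple state value into the go action weight, and an irreducible-noise
(lapse) mixture on the softmax:

    Q_t(a,s) = Q_{t-1}(a,s) + eps * (rho * r_t - Q_{t-1}(a,s))
    V_t(s)   = V_{t-1}(s)   + eps * (rho * r_t - V_{t-1}(s))
    W(go,s)  = Q(go,s) + b + pi_v * V(s);   W(nogo,s) = Q(nogo,s)
    p(go|s)  = (1 - xi) * softmax(W)_go + xi / 2

with r in {+1, 0, -1}, rho = rho_rew on win cues and rho_pun on avoid cues,
and pi_v = pi_rew (win) or pi_pun (avoid).  Q and V start at zero each
session.  Seven parameters per session; a two-session subject carries the
session-1 vector plus seven additive deltas on the unconstrained scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .task import (
    Action,
    CONDITIONS,
    CueCondition,
    TaskDesign,
    TrialRecord,
    Valence,
    condition_index,
    correct_action,
    generate_trial_sequence,
    sample_outcome,
)

__all__ = [
    "PARAM_NAMES",
    "DELTA_NAMES",
    "SUBJECT_PARAM_NAMES",
    "SessionParameters",
    "SubjectParameters",
    "LatentState",
    "transform",
    "inverse_transform",
    "session2_parameters",
    "update_values",
    "action_weights",
    "choice_probability",
    "session_loglik",
    "simulate_session",
]

#: Unconstrained parameter order used throughout the package.
PARAM_NAMES: tuple[str, ...] = ("eps", "rho_rew", "rho_pun", "go_bias", "pi_rew", "pi_pun", "xi")
DELTA_NAMES: tuple[str, ...] = tuple("d_" + n for n in PARAM_NAMES)
#: The 14 subject-level parameters of the two-session model.
SUBJECT_PARAM_NAMES: tuple[str, ...] = PARAM_NAMES + DELTA_NAMES


@dataclass(frozen=True)
class SessionParameters:
    """Natural-space parameters governing one session of behavior."""

    eps: float        # learning rate, (0, 1)
    rho_rew: float    # reward sensitivity, > 0
    rho_pun: float    # punishment sensitivity, > 0
    go_bias: float    # additive preference for go, unbounded
    pi_rew: float     # Pavlovian bias, win cues, unbounded
    pi_pun: float     # Pavlovian bias, avoid cues, unbounded
    xi: float         # irreducible noise (lapse weight), (0, 1)

    def __post_init__(self) -> None:
        if not (0.0 < self.eps < 1.0):
            raise ValueError(f"eps must lie in (0,1), got {self.eps}")
        if not (0.0 < self.xi <= 1.0):
            raise ValueError(f"xi must lie in (0,1], got {self.xi}")
        if self.rho_rew <= 0 or self.rho_pun <= 0:
            raise ValueError("outcome sensitivities must be positive")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.eps, self.rho_rew, self.rho_pun, self.go_bias, self.pi_rew, self.pi_pun, self.xi]
        )


@dataclass(frozen=True)
class SubjectParameters:
    """Session-1 unconstrained 7-vector plus 7 unconstrained deltas."""

    eta1: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        for name in ("eta1", "delta"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (7,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 7-vector")
            object.__setattr__(self, name, v)

    def session1(self) -> SessionParameters:
        return transform(self.eta1)

    def session2(self) -> SessionParameters:
        return session2_parameters(self)


def transform(eta: np.ndarray) -> SessionParameters:
    """Map an unconstrained 7-vector to natural space.

    eps and xi go through the probit (standard-normal CDF), the two
    sensitivities through exp; go bias and the Pavlovian biases are
    identity-mapped.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (7,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 7-vector")
    return SessionParameters(
        eps=float(ndtr(eta[0])),
        rho_rew=float(np.exp(eta[1])),
        rho_pun=float(np.exp(eta[2])),
        go_bias=float(eta[3]),
        pi_rew=float(eta[4]),
        pi_pun=float(eta[5]),
        xi=float(ndtr(eta[6])),
    )


def inverse_transform(p: SessionParameters) -> np.ndarray:
    """Natural-space parameters back to the unconstrained 7-vector."""
    return np.array(
        [
            ndtri(p.eps),
            math.log(p.rho_rew),
            math.log(p.rho_pun),
            p.go_bias,
            p.pi_rew,
            p.pi_pun,
            ndtri(p.xi),
        ]
    )


def natural_values(eta: np.ndarray) -> np.ndarray:
    """Vectorized unconstrained -> natural map on the last axis (size 7)."""
    eta = np.asarray(eta, dtype=float)
    out = eta.copy()
    out[..., 0] = ndtr(eta[..., 0])
    out[..., 1] = np.exp(eta[..., 1])
    out[..., 2] = np.exp(eta[..., 2])
    out[..., 6] = ndtr(eta[..., 6])
    return out


def session2_parameters(p: SubjectParameters) -> SessionParameters:
    """Session-2 natural parameters: deltas added on the unconstrained scale.

    Adding before the constraint guarantees bounded parameters stay in
    range for any delta.
    """
    return transform(p.eta1 + p.delta)


@dataclass
class LatentState:
    """Action values Q (4 stimuli x 2 actions) and state values V (4 stimuli)."""

    Q: np.ndarray
    V: np.ndarray

    @classmethod
    def zeros(cls) -> "LatentState":
        return cls(Q=np.zeros((4, 2)), V=np.zeros(4))


def _rho_for(condition: CueCondition, p: SessionParameters) -> float:
    return p.rho_rew if condition.valence == Valence.WIN else p.rho_pun


def _pi_for(condition: CueCondition, p: SessionParameters) -> float:
    return p.pi_rew if condition.valence == Valence.WIN else p.pi_pun


def update_values(
    state: LatentState,
    condition: CueCondition,
    action: Action,
    outcome: int,
    p: SessionParameters,
) -> LatentState:
    """Rescorla–Wagner update of Q(a,s) and V(s) toward rho * r.

    Returns a new state; only the visited (a, s) cell of Q and the visited
    s entry of V change.  V updates on every trial regardless of action.
    """
    if outcome not in (-1, 0, 1):
        raise ValueError(f"outcome must be -1, 0 or +1, got {outcome}")
    s = condition_index(condition)
    rho = _rho_for(condition, p)
    Q = state.Q.copy()
    V = state.V.copy()
    Q[s, int(action)] += p.eps * (rho * outcome - Q[s, int(action)])
    V[s] += p.eps * (rho * outcome - V[s])
    return LatentState(Q=Q, V=V)


def action_weights(
    state: LatentState, condition: CueCondition, p: SessionParameters
) -> tuple[float, float]:
    """(W_go, W_nogo) for a cue: go weight carries the go bias and pi_v * V."""
    s = condition_index(condition)
    w_go = state.Q[s, int(Action.GO)] + p.go_bias + _pi_for(condition, p) * state.V[s]
    w_nogo = state.Q[s, int(Action.NOGO)]
    return float(w_go), float(w_nogo)


def choice_probability(w_go: float, w_nogo: float, xi: float) -> float:
    """Lapse-mixed softmax go probability: (1 - xi) * softmax + xi / 2."""
    if not (math.isfinite(w_go) and math.isfinite(w_nogo)):
        raise ValueError("action weights must be finite")
    return (1.0 - xi) * float(expit(w_go - w_nogo)) + xi / 2.0


def _check_sorted(trials: list[TrialRecord]) -> None:
    idx = [t.trial for t in trials]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("trials must be sorted by trial index without duplicates")


def session_loglik(trials: list[TrialRecord], p: SessionParameters) -> float:
    """Log-likelihood of one subject-session under the model.

    Values start at zero, each trial contributes log p(observed response),
    and learning uses the observed outcome.
    """
    _check_sorted(trials)
    state = LatentState.zeros()
    ll = 0.0
    for t in trials:
        p_go = choice_probability(*action_weights(state, t.condition, p), p.xi)
        ll += math.log(p_go if t.response == Action.GO else 1.0 - p_go)
        state = update_values(state, t.condition, t.response, t.outcome, p)
    return ll


def simulate_session(
    p: SessionParameters,
    design: TaskDesign = TaskDesign(),
    seed: int | np.random.Generator = 0,
    subject: str = "sim",
    session: int = 1,
) -> list[TrialRecord]:
    """Generate one session of behavior from the model (fully seeded)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sequence = generate_trial_sequence(design, rng)
    state = LatentState.zeros()
    records: list[TrialRecord] = []
    for i, cond in enumerate(sequence):
        p_go = choice_probability(*action_weights(state, cond, p), p.xi)
        action = Action.GO if rng.random() < p_go else Action.NOGO
        outcome = sample_outcome(cond, action, rng.random(), design)
        records.append(
            TrialRecord(
                subject=subject, session=session, trial=i,
                condition=cond, response=action, outcome=outcome,
            )
        )
        state = update_values(state, cond, action, outcome, p)
    return records
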
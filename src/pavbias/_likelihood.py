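"""Fast likelihood and analytic gradients for the go/no-go RL model.

The hierarchical sampler needs the log-likelihood of every subject and its
gradient with respect to the 14 unconstrained subject-level parameters at
each leapfrog step.  Both are computed in one forward pass per session:
alongside Q and V we carry their sensitivities with respect to the learning
rate and the two outcome sensitivities (the only parameters the value
recursion depends on), which makes the per-trial gradient exact without
automatic differentiation.

Trials are packed into flat int64 arrays (condition index 0..3 in the
canonical order go-win, nogo-win, go-avoid, nogo-avoid; response 0/1;
outcome -1/0/+1) with per-subject, per-session start/length tables.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .task import CONDITION_TOKENS

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@njit(cache=False)
def _phi(x: float) -> float:
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=False)
def _phi_pdf(x: float) -> float:
    return math.exp(-0.5 * x * x) * _INV_SQRT_2PI


@njit(cache=False)
def _session_ll_grad_nat(cond, resp, outc, theta, g_nat):
    """One session's log-likelihood and gradient w.r.t. natural parameters.

    theta = (eps, rho_rew, rho_pun, b, pi_rew, pi_pun, xi).  Win cues are
    condition indices 0 and 1.  Gradient is accumulated into ``g_nat``.
    """
    eps = theta[0]
    rho_rew = theta[1]
    rho_pun = theta[2]
    b = theta[3]
    pi_rew = theta[4]
    pi_pun = theta[5]
    xi = theta[6]

    Q = np.zeros((4, 2))
    V = np.zeros(4)
    # sensitivities of Q and V w.r.t. eps, rho_rew, rho_pun
    sQe = np.zeros((4, 2))
    sQr = np.zeros((4, 2))
    sQp = np.zeros((4, 2))
    sVe = np.zeros(4)
    sVr = np.zeros(4)
    sVp = np.zeros(4)

    ll = 0.0
    for t in range(cond.shape[0]):
        s = cond[t]
        a = resp[t]
        r = outc[t]
        win = s <= 1
        piv = pi_rew if win else pi_pun
        rho = rho_rew if win else rho_pun

        d = Q[s, 1] + b + piv * V[s] - Q[s, 0]
        if d >= 0.0:
            sig = 1.0 / (1.0 + math.exp(-d))
        else:
            e = math.exp(d)
            sig = e / (1.0 + e)
        p_go = (1.0 - xi) * sig + 0.5 * xi

        c = (1.0 - xi) * sig * (1.0 - sig)
        dp0 = c * (sQe[s, 1] + piv * sVe[s] - sQe[s, 0])
        dp1 = c * (sQr[s, 1] + piv * sVr[s] - sQr[s, 0])
        dp2 = c * (sQp[s, 1] + piv * sVp[s] - sQp[s, 0])
        dp3 = c
        dp4 = c * V[s] if win else 0.0
        dp5 = 0.0 if win else c * V[s]
        dp6 = 0.5 - sig

        if a == 1:
            pa = p_go
            sgn = 1.0
        else:
            pa = 1.0 - p_go
            sgn = -1.0
        # guard against exact zeros under extreme proposals
        if pa < 1e-300:
            pa = 1e-300
        w = sgn / pa
        ll += math.log(pa)
        g_nat[0] += w * dp0
        g_nat[1] += w * dp1
        g_nat[2] += w * dp2
        g_nat[3] += w * dp3
        g_nat[4] += w * dp4
        g_nat[5] += w * dp5
        g_nat[6] += w * dp6

        # Rescorla-Wagner updates and their sensitivities
        pe_q = rho * r - Q[s, a]
        pe_v = rho * r - V[s]
        keep = 1.0 - eps
        sQe[s, a] = keep * sQe[s, a] + pe_q
        sVe[s] = keep * sVe[s] + pe_v
        if win:
            sQr[s, a] = keep * sQr[s, a] + eps * r
            sVr[s] = keep * sVr[s] + eps * r
            sQp[s, a] = keep * sQp[s, a]
            sVp[s] = keep * sVp[s]
        else:
            sQp[s, a] = keep * sQp[s, a] + eps * r
            sVp[s] = keep * sVp[s] + eps * r
            sQr[s, a] = keep * sQr[s, a]
            sVr[s] = keep * sVr[s]
        Q[s, a] += eps * pe_q
        V[s] += eps * pe_v
    return ll


@njit(cache=False)
def _session_ll_grad(cond, resp, outc, eta, g_eta):
    """Session log-likelihood with gradient w.r.t. the unconstrained 7-vector."""
    theta = np.empty(7)
    theta[0] = _phi(eta[0])
    theta[1] = math.exp(eta[1])
    theta[2] = math.exp(eta[2])
    theta[3] = eta[3]
    theta[4] = eta[4]
    theta[5] = eta[5]
    theta[6] = _phi(eta[6])
    g_nat = np.zeros(7)
    ll = _session_ll_grad_nat(cond, resp, outc, theta, g_nat)
    g_eta[0] += g_nat[0] * _phi_pdf(eta[0])
    g_eta[1] += g_nat[1] * theta[1]
    g_eta[2] += g_nat[2] * theta[2]
    g_eta[3] += g_nat[3]
    g_eta[4] += g_nat[4]
    g_eta[5] += g_nat[5]
    g_eta[6] += g_nat[6] * _phi_pdf(eta[6])
    return ll


@njit(cache=False)
def subject_ll_grad(c1, r1, o1, c2, r2, o2, eta14, grad14):
    """Two-session subject log-likelihood; deltas add on the unconstrained scale."""
    ll = _session_ll_grad(c1, r1, o1, eta14[:7], grad14[:7])
    if c2.shape[0] > 0:
        eta2 = eta14[:7] + eta14[7:]
        g2 = np.zeros(7)
        ll += _session_ll_grad(c2, r2, o2, eta2, g2)
        for k in range(7):
            grad14[k] += g2[k]
            grad14[7 + k] += g2[k]
    return ll


@njit(cache=False)
def cohort_ll_grad(cond, resp, outc, starts, lengths, etas, grads):
    """Total log-likelihood over subjects; per-subject gradients into ``grads``."""
    n = etas.shape[0]
    total = 0.0
    for i in range(n):
        s1 = starts[i, 0]
        l1 = lengths[i, 0]
        s2 = starts[i, 1]
        l2 = lengths[i, 1]
        grads[i, :] = 0.0
        total += subject_ll_grad(
            cond[s1 : s1 + l1], resp[s1 : s1 + l1], outc[s1 : s1 + l1],
            cond[s2 : s2 + l2], resp[s2 : s2 + l2], outc[s2 : s2 + l2],
            etas[i], grads[i],
        )
    return total


class PackedTrials:
    """Flat-array view of a long-format trial table, ordered by subject."""

    def __init__(self, trials: pd.DataFrame, subjects: list | None = None):
        required = {"subject", "session", "trial", "condition", "response", "outcome"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        if subjects is None:
            subjects = list(pd.unique(trials["subject"]))
        self.subjects = list(subjects)
        n = len(self.subjects)

        tok_to_idx = {t: i for i, t in enumerate(CONDITION_TOKENS)}
        conds, resps, outcs = [], [], []
        self.starts = np.zeros((n, 2), dtype=np.int64)
        self.lengths = np.zeros((n, 2), dtype=np.int64)
        pos = 0
        by_subject = dict(iter(trials.groupby("subject", sort=False)))
        for i, subj in enumerate(self.subjects):
            if subj not in by_subject:
                raise ValueError(f"subject {subj!r} has no trials")
            sub = by_subject[subj]
            for j, sess in enumerate((1, 2)):
                block = sub[sub["session"] == sess].sort_values("trial")
                idx = block["trial"].to_numpy()
                if len(idx) and (len(np.unique(idx)) != len(idx)):
                    raise ValueError(f"duplicate trial indices for subject {subj!r} session {sess}")
                self.starts[i, j] = pos
                self.lengths[i, j] = len(block)
                conds.append(block["condition"].map(tok_to_idx).to_numpy(dtype=np.int64))
                resps.append((block["response"] == "go").to_numpy(dtype=np.int64))
                outcs.append(block["outcome"].to_numpy(dtype=np.int64))
                pos += len(block)
        self.cond = np.concatenate(conds) if conds else np.zeros(0, dtype=np.int64)
        self.resp = np.concatenate(resps) if resps else np.zeros(0, dtype=np.int64)
        self.outc = np.concatenate(outcs) if outcs else np.zeros(0, dtype=np.int64)
        if np.any(pd.isna(self.cond)):
            raise ValueError("unknown condition token in trial table")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def loglik_and_grad(self, etas: np.ndarray) -> tuple[float, np.ndarray]:
        """Total log-likelihood and per-subject 14-parameter gradients."""
        etas = np.ascontiguousarray(etas, dtype=np.float64)
        grads = np.zeros_like(etas)
        ll = cohort_ll_grad(
            self.cond, self.resp, self.outc, self.starts, self.lengths, etas, grads
        )
        return float(ll), grads
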
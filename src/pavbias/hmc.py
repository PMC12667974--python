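"""Hamiltonian Monte Carlo with dual-averaging step-size and diagonal mass
adaptation.

A compact, dependency-free sampler sufficient for the smooth, close-to-
Gaussian posteriors produced by the non-centered hierarchical model.  The
trajectory length is held at roughly ``traj_length`` in position space
(number of leapfrog steps = trajectory length / step size, jittered) and
the step size is tuned during warmup to a target acceptance statistic.
Mass-matrix (diagonal) estimates are refreshed twice during warmup from
the accumulated draw variance, Stan-style regularized toward unity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCChain", "run_hmc_chain"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCChain:
    """Post-warmup draws and sampler statistics for one chain."""

    draws: np.ndarray          # (n_kept, dim)
    accept_rate: float
    divergences: int
    step_size: float
    logp: np.ndarray           # (n_kept,)


def _leapfrog(logp_grad: LogpGrad, x, p, grad, step, inv_mass, n_steps):
    x = x.copy()
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        x = x + step * inv_mass * p
        logp, grad = logp_grad(x)
        if not np.isfinite(logp):
            return x, p, logp, grad
        p = p + (step if i < n_steps - 1 else 0.5 * step) * grad
    return x, p, logp, grad


def _find_initial_step(logp_grad, x0, inv_mass, rng, step=1.0):
    """Double/halve the step until one leapfrog step has accept prob near 0.5."""
    logp0, grad0 = logp_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * np.sum(inv_mass * p0 * p0)

    def accept_logprob(s):
        x1, p1, logp1, _ = _leapfrog(logp_grad, x0, p0, grad0, s, inv_mass, 1)
        if not np.isfinite(logp1):
            return -np.inf
        with np.errstate(over="ignore"):
            h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        return h1 - h0

    a = accept_logprob(step)
    direction = 1.0 if a > np.log(0.5) else -1.0
    for _ in range(50):
        step *= 2.0 ** direction
        a = accept_logprob(step)
        if not np.isfinite(a):
            a = -np.inf
        if (direction == 1.0 and a <= np.log(0.5)) or (
            direction == -1.0 and a > np.log(0.5)
        ):
            break
    return step


class _DualAveraging:
    """Nesterov dual averaging of log step size (standard constants)."""

    def __init__(self, step0: float, target: float):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.log_step = np.log(step0)
        self.log_step_bar = np.log(step0)
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - eta) * self.h_bar + eta * (self.target - accept_prob)
        self.log_step = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_step_bar = w * self.log_step + (1.0 - w) * self.log_step_bar
        return float(np.exp(self.log_step))

    @property
    def adapted_step(self) -> float:
        return float(np.exp(self.log_step_bar))


def run_hmc_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    traj_length: float = 4.0,
    max_leapfrog: int = 80,
    divergence_threshold: float = 1000.0,
) -> HMCChain:
    """Run one HMC chain; returns the post-warmup draws.

    ``n_iter`` counts total iterations including ``n_warmup``.  Diagonal
    mass updates happen at 50% and 85% of warmup; step-size adaptation
    restarts after each update.
    """
    if n_iter <= n_warmup:
        raise ValueError("n_iter must exceed n_warmup")
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)

    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    step = _find_initial_step(logp_grad, x, inv_mass, rng)
    da = _DualAveraging(step, target_accept)

    mass_updates = {int(0.5 * n_warmup), int(0.85 * n_warmup)} if n_warmup >= 20 else set()
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    kept = np.empty((n_iter - n_warmup, dim))
    kept_logp = np.empty(n_iter - n_warmup)
    n_accept = 0
    n_divergent = 0

    for it in range(n_iter):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(inv_mass * p0 * p0)
        jitter = rng.uniform(0.8, 1.2)
        n_steps = int(np.clip(np.ceil(jitter * traj_length / step), 1, max_leapfrog))
        x1, p1, logp1, grad1 = _leapfrog(logp_grad, x, p0, grad, step, inv_mass, n_steps)

        if np.isfinite(logp1):
            with np.errstate(over="ignore"):
                h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
            delta_h = h1 - h0
        else:
            delta_h = -np.inf
        divergent = not np.isfinite(delta_h) or (-delta_h > divergence_threshold)
        accept_prob = 0.0 if divergent else min(1.0, float(np.exp(min(delta_h, 0.0))))

        if not divergent and np.log(rng.random()) < delta_h:
            x, logp, grad = x1, logp1, grad1
            if it >= n_warmup:
                n_accept += 1
        if divergent and it >= n_warmup:
            n_divergent += 1

        if it < n_warmup:
            step = da.update(accept_prob)
            welford_n += 1
            d = x - welford_mean
            welford_mean += d / welford_n
            welford_m2 += d * (x - welford_mean)
            if it in mass_updates and welford_n > 4:
                var = welford_m2 / (welford_n - 1)
                w = welford_n / (welford_n + 5.0)
                inv_mass = w * var + (1.0 - w) * 1.0
                inv_mass = np.maximum(inv_mass, 1e-8)
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                step = _find_initial_step(logp_grad, x, inv_mass, rng)
                da = _DualAveraging(step, target_accept)
            if it == n_warmup - 1:
                step = da.adapted_step
        else:
            kept[it - n_warmup] = x
            kept_logp[it - n_warmup] = logp

    n_kept = n_iter - n_warmup
    return HMCChain(
        draws=kept,
        accept_rate=n_accept / max(n_kept, 1),
        divergences=n_divergent,
        step_size=step,
        logp=kept_logp,
    )
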
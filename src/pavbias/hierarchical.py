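"""Hierarchical Bayesian estimation of the two-session go/no-go model.

Subjects contribute a session log-likelihood per session through the RL
model; the 14 unconstrained subject-level parameters (7 session-1 values
plus 7 session deltas) are partially pooled toward group-level normal
distributions.  The sampler works on the non-centered ("Matt trick")
parameterization

    eta_ik = mu_k (+ group / covariate terms) + sigma_k * z_ik,
    z_ik ~ Normal(0, 1),

with weakly informative priors mu_k ~ Normal(0, 1) and
sigma_k ~ half-Normal(1) on the unconstrained scale.  A centered
parameterization is available for cross-checks.  Estimation is
Hamiltonian Monte Carlo with adapted step size and diagonal mass;
convergence is assessed with classic split R-hat against the 1.1 bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._likelihood import PackedTrials, subject_ll_grad
from .agent import (
    DELTA_NAMES,
    PARAM_NAMES,
    SUBJECT_PARAM_NAMES,
    SubjectParameters,
    natural_values,
)
from .hmc import HMCChain, run_hmc_chain

__all__ = [
    "HierarchicalGNG",
    "HierarchicalGNGResults",
    "PosteriorDraws",
    "FitDiagnostics",
    "split_rhat",
    "effective_sample_size",
    "hdi",
    "summarize",
    "map_estimate",
    "sample_posterior",
]

K = len(SUBJECT_PARAM_NAMES)  # 14 subject-level parameters


# ---------------------------------------------------------------------------
# posterior summaries


def split_rhat(draws: np.ndarray) -> float:
    """Classic split-chain Gelman–Rubin potential scale reduction.

    ``draws`` has shape (chains, iterations).  Each chain is halved, the
    between- and within-half-chain variances B and W are combined as
    sqrt(((n-1)/n * W + B/n) / W).  Returns NaN for (near-)constant draws,
    which have no defined scale reduction.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("split_rhat needs draws shaped (chains >= 2, iterations)")
    if draws.shape[1] < 4:
        raise ValueError("need at least 4 iterations per chain")
    half = draws.shape[1] // 2
    chains = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    n = chains.shape[1]
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    w = variances.mean()
    if w < 1e-300 or not np.isfinite(w):
        return float("nan")
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(draws: np.ndarray) -> float:
    """Multi-chain effective sample size via Geyer's initial monotone sequence."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[None, :]
    m, n = draws.shape
    if n < 4:
        return float(m * n)
    centered = draws - draws.mean(axis=1, keepdims=True)
    # chain-averaged autocovariance via FFT
    size = int(2 ** np.ceil(np.log2(2 * n)))
    fft = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(fft * np.conj(fft), n=size, axis=1)[:, :n].real / n
    w = draws.var(axis=1, ddof=1).mean()
    b = draws.mean(axis=1).var(ddof=1) * n if m > 1 else 0.0
    var_plus = (n - 1) / n * draws.var(axis=1, ddof=0).mean() + (b / n if m > 1 else 0.0)
    if var_plus < 1e-300:
        return float("nan")
    rho = 1.0 - (w - acov.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 1.0
    prev_pair = np.inf
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1] if t + 1 < n else rho[t]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        prev_pair = pair
        tau += 2.0 * pair
    return float(m * n / max(tau, 1e-12))


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Ties in width resolve to the earliest (lowest) window.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError(f"hdi needs at least 20 draws, got {n}")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize(draws: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Median, 50%/95% HDIs and P(>0) for each named draw vector."""
    rows = []
    for name, d in draws.items():
        flat = np.asarray(d, dtype=float).ravel()
        lo50, hi50 = hdi(flat, 0.50)
        lo95, hi95 = hdi(flat, 0.95)
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(flat)),
                "hdi50_lo": lo50,
                "hdi50_hi": hi50,
                "hdi95_lo": lo95,
                "hdi95_hi": hi95,
                "p_gt_zero": float(np.mean(flat > 0)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# containers


class PosteriorDraws:
    """Labeled per-chain MCMC draws: name -> array of shape (chains, iterations)."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self._arrays = arrays
        shapes = {a.shape for a in arrays.values()}
        if len(shapes) > 1:
            raise ValueError("all draw arrays must share (chains, iterations) shape")

    @property
    def names(self) -> list[str]:
        return list(self._arrays)

    def get(self, name: str) -> np.ndarray:
        return self._arrays[name]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat vector."""
        return self._arrays[name].ravel()

    def items(self):
        return self._arrays.items()

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        frames = []
        for name, arr in self._arrays.items():
            c, n = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), n),
                        "iteration": np.tile(np.arange(n), c),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class FitDiagnostics:
    """Split R-hat and effective sample size per labeled parameter."""

    table: pd.DataFrame           # index parameter, columns rhat, ess
    max_rhat: float
    divergences: int
    settings: dict = field(default_factory=dict)

    def converged(self, threshold: float = 1.1) -> bool:
        return bool(self.max_rhat <= threshold)


# ---------------------------------------------------------------------------
# the model


class HierarchicalGNG:
    """Hierarchical two-session go/no-go model (statsmodels-style).

    Parameters
    ----------
    trials : DataFrame
        Long-format trial table (subject, session, trial, condition token,
        response, outcome).  Every subject needs session-1 trials;
        session-2 trials are optional.
    groups : mapping or Series, optional
        Subject -> group label.  When given, each group gets its own
        vector of 14 group means (shared group SDs), so group contrasts
        have joint posteriors.
    covariates : DataFrame, optional
        Subject-indexed covariates entering the group means linearly;
        columns are z-scored internally.
    centered : bool
        Use the centered parameterization instead of the non-centered
        default (cross-check mode).
    """

    #: Number of subject-level parameters in the two-session model.
    n_subject_parameters = K

    def __init__(
        self,
        trials: pd.DataFrame,
        groups: Mapping | pd.Series | None = None,
        covariates: pd.DataFrame | None = None,
        centered: bool = False,
        prior_mu_scale: float = 1.0,
        prior_sigma_scale: float = 1.0,
    ):
        self.packed = PackedTrials(trials)
        if np.any(self.packed.lengths[:, 0] == 0):
            bad = [s for s, l in zip(self.packed.subjects, self.packed.lengths[:, 0]) if l == 0]
            raise ValueError(f"subjects without session-1 trials: {bad}")
        self.subjects = self.packed.subjects
        n = len(self.subjects)

        if groups is not None:
            groups = dict(groups) if not isinstance(groups, pd.Series) else groups.to_dict()
            missing = [s for s in self.subjects if s not in groups]
            if missing:
                raise ValueError(f"subjects missing a group label: {missing}")
            self.group_labels = sorted({groups[s] for s in self.subjects}, key=str)
            self.group_index = np.array(
                [self.group_labels.index(groups[s]) for s in self.subjects]
            )
        else:
            self.group_labels = [None]
            self.group_index = np.zeros(n, dtype=int)

        if covariates is not None and len(covariates.columns) > 0:
            cov = covariates.loc[list(self.subjects)].astype(float)
            x = cov.to_numpy()
            sd = x.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise ValueError("constant covariate column")
            self.X = (x - x.mean(axis=0)) / sd
            self.covariate_names = list(cov.columns)
        else:
            self.X = np.zeros((n, 0))
            self.covariate_names = []

        self.centered = centered
        self.prior_mu_scale = float(prior_mu_scale)
        self.prior_sigma_scale = float(prior_sigma_scale)
        self.n_groups = len(self.group_labels)
        self.n_covariates = len(self.covariate_names)
        self._g = self.n_groups * K
        self._c = self.n_covariates * K

    # -- layout ------------------------------------------------------------

    @property
    def n_free_parameters(self) -> int:
        """Free quantities sampled: group means, covariate slopes, SDs, z-scores."""
        return self._g + self._c + K + len(self.subjects) * K

    def _unpack(self, x: np.ndarray):
        g, c = self._g, self._c
        mu = x[:g].reshape(self.n_groups, K)
        beta = x[g : g + c].reshape(self.n_covariates, K)
        ls = x[g + c : g + c + K]
        z = x[g + c + K :].reshape(len(self.subjects), K)
        return mu, beta, ls, z

    def _mean_matrix(self, mu: np.ndarray, beta: np.ndarray) -> np.ndarray:
        m = mu[self.group_index]
        if self.n_covariates:
            m = m + self.X @ beta
        return m

    def subject_eta(self, x: np.ndarray) -> np.ndarray:
        """(n_subjects, 14) unconstrained parameters implied by a draw."""
        mu, beta, ls, z = self._unpack(x)
        if self.centered:
            return z
        return self._mean_matrix(mu, beta) + np.exp(ls) * z

    # -- log posterior -----------------------------------------------------

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore"):
            return self._logp_and_grad(x)

    def _logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        mu, beta, ls, z = self._unpack(x)
        if np.any(ls < -300.0):  # sigma underflow: reject cleanly
            return -np.inf, np.zeros_like(x)
        sigma = np.exp(ls)
        m = self._mean_matrix(mu, beta)
        eta = z if self.centered else m + sigma * z
        ll, g_eta = self.packed.loglik_and_grad(eta)

        s_mu, s_sig = self.prior_mu_scale, self.prior_sigma_scale
        logp = ll - 0.5 * np.sum(mu**2) / s_mu**2 - 0.5 * np.sum(beta**2)
        # half-normal prior on sigma plus log|d sigma / d log sigma|
        logp += np.sum(-0.5 * sigma**2 / s_sig**2 + ls)

        grad = np.empty_like(x)
        g, c = self._g, self._c
        d_mu = np.zeros_like(mu)
        d_beta = np.zeros_like(beta)
        if self.centered:
            resid = (eta - m) / sigma**2
            logp += float(np.sum(-0.5 * (eta - m) ** 2 / sigma**2 - ls))
            d_z = g_eta - resid
            np.add.at(d_mu, self.group_index, resid)
            if self.n_covariates:
                d_beta += self.X.T @ resid
            d_ls = np.sum((eta - m) ** 2 / sigma**2 - 1.0, axis=0)
        else:
            logp += float(-0.5 * np.sum(z**2))
            d_z = g_eta * sigma - z
            np.add.at(d_mu, self.group_index, g_eta)
            if self.n_covariates:
                d_beta += self.X.T @ g_eta
            d_ls = np.sum(g_eta * z, axis=0) * sigma
        d_mu -= mu / s_mu**2
        d_beta -= beta
        d_ls += -(sigma**2) / s_sig**2 + 1.0
        grad[:g] = d_mu.ravel()
        grad[g : g + c] = d_beta.ravel()
        grad[g + c : g + c + K] = d_ls
        grad[g + c + K :] = d_z.ravel()
        return float(logp), grad

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        chains: int = 2,
        iterations: int = 600,
        warmup: int = 300,
        seed: int = 0,
        target_accept: float = 0.9,
        traj_length: float = 4.0,
        max_leapfrog: int = 80,
    ) -> "HierarchicalGNGResults":
        """Sample the posterior with HMC.

        Defaults are the reduced desk scale (2 chains x 600 iterations,
        300 warmup); pass ``chains=4, iterations=4000, warmup=2000`` for
        full-scale runs.
        """
        if chains < 2:
            warnings.warn("fewer than 2 chains: R-hat will be undefined", stacklevel=2)
        seeds = np.random.SeedSequence(seed).spawn(chains)
        chain_results: list[HMCChain] = []
        for ch in range(chains):
            rng = np.random.default_rng(seeds[ch])
            x0 = 0.2 * rng.standard_normal(self.n_free_parameters)
            g, c = self._g, self._c
            x0[g + c : g + c + K] = -1.0 + 0.1 * rng.standard_normal(K)
            if self.centered:
                x0[g + c + K :] = 0.1 * rng.standard_normal(len(self.subjects) * K)
            chain_results.append(
                run_hmc_chain(
                    self.logp_and_grad,
                    x0,
                    n_iter=iterations,
                    n_warmup=warmup,
                    rng=rng,
                    target_accept=target_accept,
                    traj_length=traj_length,
                    max_leapfrog=max_leapfrog,
                )
            )
        settings = dict(
            chains=chains, iterations=iterations, warmup=warmup, seed=seed,
            target_accept=target_accept, parameterization="centered" if self.centered else "non-centered",
        )
        return HierarchicalGNGResults(self, chain_results, settings)

    # -- penalized point estimate -----------------------------------------

    def map_estimate(
        self, subject, penalty_scale: float = 1.0
    ) -> tuple[SubjectParameters, bool]:
        """Penalized ML point estimate for one subject (standard-normal penalty).

        Deterministic fallback to the full posterior: maximizes the
        subject's two-session log-likelihood minus ||eta/penalty_scale||^2/2
        from a zero start.  A large ``penalty_scale`` approaches plain ML
        while keeping weakly identified parameters finite.  Returns
        (estimate, converged flag); on failure the best iterate is still
        returned.
        """
        i = self.subjects.index(subject)
        p = self.packed
        s1, l1 = p.starts[i, 0], p.lengths[i, 0]
        s2, l2 = p.starts[i, 1], p.lengths[i, 1]
        args = (
            p.cond[s1 : s1 + l1], p.resp[s1 : s1 + l1], p.outc[s1 : s1 + l1],
            p.cond[s2 : s2 + l2], p.resp[s2 : s2 + l2], p.outc[s2 : s2 + l2],
        )

        inv_var = 1.0 / penalty_scale**2

        def objective(eta):
            grad = np.zeros(K)
            ll = subject_ll_grad(*args, eta, grad)
            return -(ll - 0.5 * inv_var * np.sum(eta**2)), -(grad - inv_var * eta)

        res = minimize(objective, np.zeros(K), jac=True, method="L-BFGS-B")
        est = SubjectParameters(eta1=res.x[:7], delta=res.x[7:])
        return est, bool(res.success)


def sample_posterior(
    model: HierarchicalGNG,
    chains: int = 2,
    iterations: int = 600,
    warmup: int = 300,
    seed: int = 0,
    **kwargs,
) -> "HierarchicalGNGResults":
    """Functional alias for :meth:`HierarchicalGNG.fit`."""
    return model.fit(chains=chains, iterations=iterations, warmup=warmup, seed=seed, **kwargs)


def map_estimate(model: HierarchicalGNG, subject) -> tuple[SubjectParameters, bool]:
    """Functional alias for :meth:`HierarchicalGNG.map_estimate`."""
    return model.map_estimate(subject)


# ---------------------------------------------------------------------------
# results


class HierarchicalGNGResults:
    """Posterior draws, diagnostics and summaries for a fitted model."""

    def __init__(self, model: HierarchicalGNG, chains: list[HMCChain], settings: dict):
        self.model = model
        self._chains = chains
        self.settings = settings
        self._x = np.stack([c.draws for c in chains])  # (chains, kept, dim)
        self.divergences = int(sum(c.divergences for c in chains))
        self._posterior: PosteriorDraws | None = None
        self._eta: np.ndarray | None = None
        self._diagnostics: FitDiagnostics | None = None

    # -- labeled draws -----------------------------------------------------

    def _label(self, kind: str, *parts: str) -> str:
        return kind + "".join(f"[{p}]" for p in parts if p is not None)

    @property
    def eta_draws(self) -> np.ndarray:
        """(chains, kept, n_subjects, 14) subject-level unconstrained draws."""
        if self._eta is None:
            c, n, _ = self._x.shape
            out = np.empty((c, n, len(self.model.subjects), K))
            for i in range(c):
                for j in range(n):
                    out[i, j] = self.model.subject_eta(self._x[i, j])
            self._eta = out
        return self._eta

    @property
    def posterior(self) -> PosteriorDraws:
        if self._posterior is None:
            m = self.model
            arrays: dict[str, np.ndarray] = {}
            g, c = m._g, m._c
            mu = self._x[:, :, :g].reshape(*self._x.shape[:2], m.n_groups, K)
            for gi, glabel in enumerate(m.group_labels):
                for k, pname in enumerate(SUBJECT_PARAM_NAMES):
                    key = self._label("mu", None if glabel is None else str(glabel), pname)
                    arrays[key] = mu[:, :, gi, k]
            beta = self._x[:, :, g : g + c].reshape(*self._x.shape[:2], m.n_covariates, K)
            for ci, cname in enumerate(m.covariate_names):
                for k, pname in enumerate(SUBJECT_PARAM_NAMES):
                    arrays[self._label("beta", cname, pname)] = beta[:, :, ci, k]
            for k, pname in enumerate(SUBJECT_PARAM_NAMES):
                arrays[f"sigma[{pname}]"] = np.exp(self._x[:, :, g + c + k])
            eta = self.eta_draws
            for si, subj in enumerate(m.subjects):
                for k, pname in enumerate(SUBJECT_PARAM_NAMES):
                    arrays[self._label("eta", str(subj), pname)] = eta[:, :, si, k]
            self._posterior = PosteriorDraws(arrays)
        return self._posterior

    # -- diagnostics -------------------------------------------------------

    @property
    def diagnostics(self) -> FitDiagnostics:
        if self._diagnostics is None:
            rows = []
            for name, arr in self.posterior.items():
                rows.append(
                    {
                        "parameter": name,
                        "rhat": split_rhat(arr) if arr.shape[0] >= 2 else float("nan"),
                        "ess": effective_sample_size(arr),
                    }
                )
            table = pd.DataFrame(rows).set_index("parameter")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                max_rhat = float(np.nanmax(table["rhat"].to_numpy()))
            self._diagnostics = FitDiagnostics(
                table=table,
                max_rhat=max_rhat,
                divergences=self.divergences,
                settings=dict(self.settings),
            )
        return self._diagnostics

    # -- summaries ---------------------------------------------------------

    def summary(self, kind: str = "group") -> pd.DataFrame:
        """Posterior summary table (median, 50%/95% HDI, P(>0)).

        kind='group' summarizes group-level means/SDs (plus covariate
        slopes); kind='subject' the subject-level unconstrained
        parameters.
        """
        if kind == "group":
            names = [n for n in self.posterior.names if n.startswith(("mu", "sigma", "beta"))]
        elif kind == "subject":
            names = [n for n in self.posterior.names if n.startswith("eta")]
        else:
            raise ValueError("kind must be 'group' or 'subject'")
        return summarize({n: self.posterior.get(n) for n in names})

    def group_mean_draws(self, parameter: str, group=None) -> np.ndarray:
        """Flat draws of one group-level mean (unconstrained scale)."""
        key = self._label("mu", None if group is None else str(group), parameter)
        return self.posterior.stacked(key)

    def group_delta_draws(self, group=None) -> dict[str, np.ndarray]:
        """Flat draws of the 7 group-level session deltas for one group."""
        return {name: self.group_mean_draws(name, group) for name in DELTA_NAMES}

    def subject_posterior_mean(self, scale: str = "unconstrained") -> pd.DataFrame:
        """Posterior means of subject-level parameters.

        scale='unconstrained' returns the 14-vector per subject;
        scale='natural' returns natural-space parameters for both sessions
        (columns suffixed _s1 / _s2).
        """
        eta = self.eta_draws.reshape(-1, len(self.model.subjects), K)
        if scale == "unconstrained":
            mean = eta.mean(axis=0)
            return pd.DataFrame(mean, index=self.model.subjects, columns=SUBJECT_PARAM_NAMES)
        if scale != "natural":
            raise ValueError("scale must be 'unconstrained' or 'natural'")
        nat1 = natural_values(eta[:, :, :7]).mean(axis=0)
        nat2 = natural_values(eta[:, :, :7] + eta[:, :, 7:]).mean(axis=0)
        cols1 = [f"{p}_s1" for p in PARAM_NAMES]
        cols2 = [f"{p}_s2" for p in PARAM_NAMES]
        return pd.DataFrame(
            np.hstack([nat1, nat2]), index=self.model.subjects, columns=cols1 + cols2
        )

    def subject_hdi(self, parameter: str, mass: float = 0.95) -> pd.DataFrame:
        """Per-subject HDI of one of the 14 unconstrained parameters."""
        k = SUBJECT_PARAM_NAMES.index(parameter)
        eta = self.eta_draws.reshape(-1, len(self.model.subjects), K)
        rows = [hdi(eta[:, i, k], mass) for i in range(len(self.model.subjects))]
        return pd.DataFrame(rows, index=self.model.subjects, columns=["lo", "hi"])

    # -- plotting ----------------------------------------------------------

    def plot_forest(self, parameters: Sequence[str] = DELTA_NAMES, ax=None):
        """Forest plot of group-level means: medians with 50%/95% HDIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * len(parameters) * max(1, self.model.n_groups) + 1))
        y = 0
        colors = ["C0", "C1", "C2"]
        for pname in parameters:
            for gi, glabel in enumerate(self.model.group_labels):
                d = self.group_mean_draws(pname, glabel)
                lo95, hi95 = hdi(d, 0.95)
                lo50, hi50 = hdi(d, 0.50)
                col = colors[gi % len(colors)]
                ax.plot([lo95, hi95], [y, y], color=col, lw=1.5, alpha=0.5)
                ax.plot([lo50, hi50], [y, y], color=col, lw=4)
                ax.plot(np.median(d), y, "o", color="white", mec=col)
                label = pname if glabel is None else f"{pname} ({glabel})"
                ax.text(ax.get_xlim()[0], y + 0.15, label, fontsize=8)
                y += 1
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks([])
        ax.set_xlabel("group-level mean (unconstrained scale)")
        return ax
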
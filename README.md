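# pavbias

Computational pipeline for quantifying **Pavlovian bias** in the
orthogonalized go/no-go task and relating it to smoking-cessation
outcomes. It is aimed at computational-psychiatry researchers who want a
tested, reproducible implementation of the full analysis chain: a
generative reinforcement-learning model of the task, hierarchical
Bayesian two-session parameter estimation, behavioral congruency
statistics, cohort quality control, and the logistic moderation analysis
linking Pavlovian bias × clinic participation to quitting — all
exercisable end to end on synthetic cohorts with known ground truth.

## The model

The task crosses required action (go / no-go) with cue valence (win /
avoid). Behavior follows a Rescorla–Wagner learner with Pavlovian
coupling: action values `Q(a,s)` and state values `V(s)` update toward
the sensitivity-scaled outcome,

    Q_t(a_t,s_t) = Q_{t-1}(a_t,s_t) + ε (ρ r_t − Q_{t-1}(a_t,s_t))
    V_t(s_t)     = V_{t-1}(s_t)     + ε (ρ r_t − V_{t-1}(s_t))

with `r ∈ {+1, 0, −1}` and `ρ = ρ_rew` (win cues) or `ρ_pun` (avoid
cues). Action weights add a go bias `b` and a valence-specific Pavlovian
term,

    W(go,s) = Q(go,s) + b + π_v V(s),      W(nogo,s) = Q(nogo,s)

and choices follow a lapse-mixed softmax
`p(go|s) = (1−ξ)·softmax(W) + ξ/2`. Seven parameters per session; a
two-session design adds seven deltas (Δ) on the unconstrained scale — 14
subject-level parameters — which are partially pooled toward group-level
normals (non-centered parameterization, probit/log constraint
transforms) and sampled with Hamiltonian Monte Carlo using analytic
likelihood gradients. Convergence is checked with split R-hat against
the 1.1 bound.

Downstream, session-1 `π_rew` enters a logistic regression of quit
success together with standardized covariates, clinic participation rate
and the participation × `π_rew` interaction; group-level Δ parameters
are assessed for credible change via 95% highest-density intervals.

## Worked example

Generate a 30-subject synthetic cohort (15 quitters with a +0.8 shift on
Δπ_rew, 15 non-quitters), fit the joint group model, and run the
downstream analyses:

```python
from pavbias import (HierarchicalGNG, condition_accuracy, congruency_contrasts,
                     credible_group_change, fit_quit_model)
from pavbias.cohort import GenerationConfig, generate_cohort

data = generate_cohort(GenerationConfig(n_quit=15, n_nonquit=15, seed=42))
print(congruency_contrasts(condition_accuracy(data.trials), session=1).round(3))

groups = {s: ("quit" if q else "nonquit")
          for s, q in zip(data.cohort["subject"], data.cohort["quit"])}
model = HierarchicalGNG(data.trials, groups=groups)
results = model.fit(chains=2, iterations=600, warmup=300, seed=1)
print("max split R-hat:", round(results.diagnostics.max_rhat, 3))

change = credible_group_change({g: results.group_delta_draws(g)
                                for g in model.group_labels})
print(change[change.parameter == "d_pi_rew"].round(3))

pi = results.subject_posterior_mean("natural")["pi_rew_s1"]
print(fit_quit_model(data.cohort, pi).table.round(3))
```

Output (abridged):

```
 session               contrast  mean1   sd1  mean2   sd2     t  df     p     d
       1     go_win_vs_nogo_win  0.824 0.117  0.675 0.188 3.283  29 0.003 0.952
       1 nogo_avoid_vs_go_avoid  0.793 0.129  0.646 0.190 3.078  29 0.005 0.907
max split R-hat: 1.022
  group parameter  median  hdi_lo  hdi_hi  credible direction
nonquit  d_pi_rew   0.034  -0.274   0.427     False  increase
   quit  d_pi_rew   0.504   0.147   0.810      True  increase
```

Reading it: simulated agents are more accurate in Pavlovian-congruent
conditions (go-to-win 0.82 vs no-go-to-win 0.68; no-go-to-avoid 0.79 vs
go-to-avoid 0.65), both contrasts significant with large effect sizes —
the behavioral signature of Pavlovian bias. The sampler converged (max
R-hat 1.02 ≤ 1.1). The group-level posterior recovers the generative
structure: the reward-domain Pavlovian bias shows a credible increase in
quitters (95% HDI 0.15–0.81, excluding zero) but not in non-quitters.
The quit-model table (10 terms mirroring the moderation analysis) is
noisy at n=30; its recovery properties are demonstrated at n=500 in the
test suite.

A `pavbias` console script wraps the same stages
(`simulate`, `fit`, `recover`, `analyze`, `report`); see
`pavbias --help`.

## Layout

```
src/pavbias/
  task.py          task design, outcome schedule, trial sequences
  agent.py         RL model: transforms, updates, likelihood, simulation
  _likelihood.py   numba kernels: likelihood + analytic gradients
  hmc.py           Hamiltonian Monte Carlo with adaptation
  hierarchical.py  HierarchicalGNG model / results, R-hat, HDI, summaries
  behavior.py      condition accuracy, congruency contrasts, effect sizes
  cessation.py     QC filters, abstinence rule, quit moderation model
  cohort.py        synthetic ground-truth cohort generator, recovery report
  io.py            CSV dialects, pipeline config, stage orchestration
  cli.py           click command-line interface
docs/methods.md    modeling and design notes
```
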
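# Methods

## The task and the behavioral model

The orthogonalized go/no-go task crosses required action (press / withhold)
with cue valence (win / avoid), yielding four cue conditions: go-to-win,
no-go-to-win, go-to-avoid-losing, no-go-to-avoid-losing. Feedback is
probabilistic: a correct response earns the optimal outcome (reward +1 on
win cues, no loss 0 on avoid cues) with probability 0.8, an incorrect
response with probability 0.2. A session has 45 trials per condition (180
total) in a uniformly shuffled order. Outcomes are coded r ∈ {+1, 0, −1};
on avoid cues the non-optimal outcome is a punishment (−1).

Behavior is modeled as a Rescorla–Wagner learner with Pavlovian coupling.
Action values Q(a, s) and state values V(s) start at zero and update after
every trial toward the sensitivity-scaled outcome ρ·r with learning rate ε
(V updates regardless of the action taken). Action weights are

    W(go, s)   = Q(go, s) + b + π_v · V(s)
    W(no-go,s) = Q(no-go, s)

with a constant go bias b and a valence-specific Pavlovian bias (π_rew on
win cues, π_pun on avoid cues) that couples state value into the go
tendency: appetitive cues invigorate responding, aversive cues suppress
it. Choice follows a lapse-mixed softmax,
p(go) = (1 − ξ)·softmax(W) + ξ/2, where ξ is the irreducible noise. ρ is
ρ_rew on win cues and ρ_pun on avoid cues; since win cues never deliver −1
and avoid cues never deliver +1, cue valence and outcome sign coincide,
and at r = 0 the ρ term vanishes, so the selection is unambiguous.

Seven parameters govern one session. For a two-session (pre/post) design,
each parameter gains an additive delta, giving 14 subject-level
parameters. All parameters live on an unconstrained scale during
estimation: ε and ξ map through the probit (standard-normal CDF), ρ_rew
and ρ_pun through exp, and b, π_rew, π_pun are identity-mapped. Deltas are
added **before** the constraint transform, so bounded parameters can never
leave their range in session 2. The alternative reading — adding deltas in
natural space — is not representable for bounded parameters without extra
constraints, which is why the pre-transform convention was adopted.

## Hierarchical estimation

Subject-level unconstrained parameters are partially pooled:

    η_ik = μ_k [+ group- or covariate-specific terms] + σ_k · z_ik,
    z_ik ~ Normal(0, 1)

(the non-centered or "Matt trick" parameterization), with weakly
informative priors μ_k ~ Normal(0, 1) and σ_k ~ half-Normal(1) on the
unconstrained scale. These prior scales are generous on the probit/log
scales involved (a Normal(0,1) probit mean spans learning rates from
≈0.02 to ≈0.98). When a quit/non-quit grouping is supplied, each group
gets its own mean vector μ while SDs are shared, so group contrasts have
joint posteriors from a single fit; a separate-fits mode is available by
simply fitting each group's subjects alone, and a centered
parameterization exists for cross-checks. Optional covariates (z-scored)
enter the group means linearly.

Sampling is Hamiltonian Monte Carlo with analytically derived gradients:
the session log-likelihood's derivatives with respect to all 14 parameters
are accumulated in the same forward pass as the value recursion (carrying
dQ/dε, dQ/dρ sensitivity tables), so no numerical or automatic
differentiation is involved. The sampler adapts its step size by dual
averaging to a 0.9 acceptance target (the usual choice for hierarchical
posteriors, whose slow direction is the group-SD "funnel") and refreshes
a diagonal mass matrix twice during warmup; trajectory length is ~4.0 in
position space with ±20% jitter, capped at 80 leapfrog steps. Energy
errors above 1000 count as divergences.

Convergence is assessed with the classic split-chain Gelman–Rubin
statistic (rank normalization off), threshold 1.1, computed for every
group-level quantity and every subject-level η; effective sample sizes
use Geyer's initial monotone sequence. Posterior summaries report the
median, 50% and 95% highest-density intervals (narrowest contiguous
window over sorted draws, earliest window on ties) and P(>0). A
penalized-ML point estimate (standard-normal penalty on η, L-BFGS from a
zero start) provides a deterministic fallback and the reference point for
shrinkage checks.

Default sampler settings are the reduced desk scale (2 chains × 600
iterations, 300 warmup), which keeps a 15-subject fit under a minute and
a 50-subject fit near one minute; full-scale runs (4 chains × 4000 / 2000
warmup) are a single argument away. The package's own validation uses the
reduced scale throughout.

## Behavioral statistics

Condition accuracy is the fraction of trials whose response matches the
condition's required action, per subject × session × condition. The
congruency contrasts (go-win vs no-go-win; no-go-avoid vs go-avoid) use a
paired t test across subjects and Cohen's d with the average-variance
pooled SD, d = (m₁ − m₂)/√((s₁² + s₂²)/2). The pooled-SD form is pinned
by the worked examples: it is the only standard d formula that reproduces
all four published (mean, SD, d) triples to two decimals. P-values are
two-sided and uncorrected.

## Cohort QC and the moderation analysis

Exclusion filters run in a fixed priority order (first match wins): raised
data-issue flag, raised low-concentration flag, go responses on more than
90% of a session's trials, any parameter split R-hat above 1.1, fewer
than 7 smoking-survey days. Filters are idempotent and partition the
cohort into retained and excluded sets. CO-verified abstinence requires
exhaled CO strictly below 5 ppm and no self-reported smoking in the last
week.

The moderation model is a maximum-likelihood logistic regression of quit
success on an intercept, smoking duration, a male indicator, BIS, KTSND,
CWS, YBOCS, clinic participation rate, session-1 π_rew (posterior mean of
the natural-scale parameter by default; the median is configurable) and
the participation × π_rew interaction. All continuous predictors are
z-scored before entry and the interaction is the product of standardized
components — this is what makes coefficients of order one comparable
across predictors measured on rates, sum scores and model parameters.
Simple slopes of participation at fixed π_rew values are
β_part + β_int·π with delta-method standard errors from the Wald
covariance. If the Newton optimizer's Hessian is numerically singular
(quasi-separation territory at small n), the fit retries with BFGS and
warns. Group-level session deltas are called credible when their 95% HDI
excludes zero.

## The synthetic cohort

The generator emulates the data-generating structure the analysis
assumes. Session-1 parameters are drawn from group normals on the
unconstrained scale with means (−0.5, 1.3, 1.3, 0.2, 0.6, 0.6, −1.2) and
SDs (0.5, 0.4, 0.4, 0.5, 0.7, 0.7, 0.3) — i.e. learning rate ≈ 0.31,
sensitivities ≈ 3.7, a modest go bias, positive Pavlovian biases and a
lapse ≈ 0.12. These means were calibrated once so that simulated
condition accuracies land where human cohorts on this task do
(≈0.61/0.84/0.74/0.64 for go-avoid / go-win / no-go-avoid / no-go-win),
with the congruent > incongruent ordering. Session-2 deltas are
group-specific: quitters get a +0.8 mean shift on Δπ_rew, all other delta
means are zero, delta SDs 0.3.

Quit outcomes follow a logistic model on standardized covariates,
participation rate, generating π_rew and their interaction, with default
coefficients echoing the fitted values a study of this design reports
(participation ≈ +1.13, interaction ≈ −0.85). Because quit status is both
an outcome of that model and the grouping variable for the deltas,
candidates are drawn sequentially and kept until each group quota is
full. This is case-control sampling: slope coefficients remain
recoverable (the intercept absorbs the sampling fraction), which the
moderation-recovery tests exploit. Covariates are independent standard
normals, participation is Beta(5, 1.5), smoking duration Normal(7.8,
3.5) years truncated at 0.5, sex male with probability 0.86. CO readings
are drawn uniform below 5 ppm for quitters and in 5–30 ppm for
non-quitters so that abstinence classification is exercised on both sides
of the threshold.

What the generator does **not** emulate: covariate correlations (all
independent), dropout and day-by-day survey dynamics, reaction times,
session-order or practice effects beyond the delta parameters, and any
imaging-related structure. Passing tests therefore demonstrate that the
estimation machinery is correct and well calibrated under the model's own
assumptions — not that the model is true of human data.

## Numerical choices and degenerate inputs

* Softmax differences are computed through a numerically stable sigmoid;
  per-trial probabilities are floored at 1e−300 before the log so extreme
  warmup proposals cannot produce non-finite likelihoods.
* Q and V initialize at zero — the neutral choice given outcome coding
  symmetric about zero.
* Split R-hat is undefined (NaN, flagged) for constant chains; the HDI
  requires ≥ 20 draws and breaks width ties toward the earliest window;
  zero-variance paired differences and double-zero SDs return NaN with a
  warning rather than raising.
* Seeds: every stochastic entry point takes an explicit seed or Generator;
  chains derive per-chain seeds via `SeedSequence.spawn`, so a fit is
  bit-reproducible given (data, settings, seed).

## Known limitations

* The lapse rate ξ (and its delta) is weakly identified from 180 trials;
  its posterior leans on the group prior, and 95% intervals for ξ
  under-cover the generating values in recovery simulations. This is a
  property of the design, not of the sampler; the recovery report states
  coverage per parameter so the effect is visible rather than hidden.
* Delta parameters for the sensitivities (Δρ) recover with modest
  correlations at 180 trials/session; group-level delta means are the
  quantities the pipeline is designed to recover well.
* HMC here uses a fixed trajectory-length heuristic rather than NUTS;
  for the posteriors this package produces (near-Gaussian after the
  non-centered transform) that is sufficient, as the R-hat/ESS
  diagnostics verify per run.
* One learning rate is shared across valences and across the Q and V
  updates; alternative model variants are out of scope.
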
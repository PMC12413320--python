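# Methods

This note documents the models, the generating conditions of the synthetic
cohort, the numerical choices behind the sampler and the estimators, and
what the validation suite does and does not establish.

## Task environment

The reversal task presents two options. On every trial the currently
"better" option has reward available with probability `p_high = 0.8` and
the other with 0.2, drawn independently per option per trial and
pre-realized in the schedule, so that replays and counterfactual updates
are well defined. The better option's identity alternates at every
multiple of `phase_length = 7` within a 28-trial block (4 phases). A
session holds one social-feedback and one non-social-feedback block in
seeded random order (56 trials); three sessions (baseline, isolation with
media access, total isolation) give six condition cells per subject.
Outcomes are coded +1 (win) and −1 (no win) because all update rules
branch on the outcome's sign; an outcome of 0 is rejected as a coding
violation. Trial and phase indices are 0-based internally and 1-based in
all exported tables.

The effort-based decision schedule is generated as a balanced, seeded
permutation of the 8 conditions (effort hard/easy × reward 4/1 points ×
context social/nature), 6 trials each, 48 in total. Button-press
calibration and point-to-money conversion are outside the package's scope;
only the condition list is produced.

## Candidate learning models

All four models update option values V from prediction errors and choose
through a softmax `p(A) = 1/(1 + exp(−β (V_A − V_B)))`:

- `rw_pn` — delta rule on the chosen option only, with separate learning
  rates η_rew (after wins) and η_nrew (after non-wins).
- `ewa` — experience-weighted attraction: the chosen option's experience
  weight decays and increments (`n ← nρ + 1`) and damps the update
  `V ← (V φ n_prev + O) / n_new`; φ decays past payoffs.
- `ewa_2lr` — the same with φ branching on the outcome sign.
- `fictitious` — delta-rule update of the chosen option toward O and of
  the unchosen option toward −O, with the learning-rate assignment
  mirrored between the two.

Initial values are V = 0 for both options and n = 1 at every block start,
and state resets between blocks and sessions (the task uses different
stimulus pairs per session, so carrying value across blocks has no
behavioral referent). Missing trials (the task imposes a 1-s response
deadline) contribute nothing to the likelihood and trigger no update. For
`rw_pn` and `fictitious` with outcomes ±1 and rates in [0, 1], values are
confined to [−1, 1]; EWA values are not clamped and can leave that range
for extreme (ρ, φ), which is documented rather than suppressed.

One typographic ambiguity in the EWA recursion — whether the payoff-decay
product is divided by the previous or the updated experience weight — is
resolved as: numerator uses `n_prev`, denominator uses `n_new`; the
alternative reading stays available through the `denom` switch of
`update_ewa`.

## Hierarchical model

All six cells are fitted jointly. The effect-coding design matrix has one
baseline column per feedback type and one difference column per isolation
session; cell values are row sums, e.g. `iso_media = baseline +
iso_media_diff`. Per model parameter there is a group mean μ_k and a
subject-level SD σ_k per design column, plus a standard-normal subject
deviation z_{s,k} per subject per column (non-centered). A subject's
unconstrained cell value is `Σ_k X[cell,k] (μ_k + σ_k z_{s,k})`, mapped
through the inverse-probit link Φ(·) for unit-interval parameters and
`U_β Φ(·)` for the inverse temperature. Making deviations per *column*
rather than per cell keeps the subject covariance structure aligned with
what the group level estimates; the alternative (shared deviations across
cells) was considered and rejected as more restrictive than the design
warrants.

`U_β = 10` by default. The grid simulation explores β up to 20, but
observed inverse temperatures in this task family concentrate well below
5, and a looser bound flattens the link around typical values; the bound
is a configuration knob (`GroupPrior.beta_upper`), not a constant.

Hyperpriors on the unconstrained scale: μ ~ Normal(0, 1), σ ~
half-Normal(0, 0.5). The Normal(0, 1) prior on probit-scale means is
close to uniform on the rate scale; half-Normal(0, 0.5) keeps subject
spread plausible (a 1-SD subject moves a rate from 0.5 to at most ~0.7)
without forbidding larger heterogeneity. Both are configurable.

### Sampler

Sampling uses an in-package No-U-Turn sampler: slice-variable tree
doubling with a maximum depth of 10, a divergence threshold of 1000 on the
joint log density, dual averaging of the step size toward a 0.9 acceptance
target, and Stan-style warmup windows (fast start, expanding slow windows,
fast tail) estimating a diagonal metric. Likelihood gradients are
analytic: the value recursion carries ∂V/∂parameter alongside V, compiled
with numba (a pure-numpy reference path exists and the two are asserted
identical in the tests). Chains are initialized near the prior center with
jittered draws and log σ near log 0.2; a non-finite initial density is
reseeded up to five times before a hard failure. Defaults are 4 chains ×
(1000 warmup + 1000 sampling); the reduced setting used in the test suite
and the acceptance script is 2 × (500 + 500) on 15 subjects, which mixes
to max split R-hat ≈ 1.02–1.03 in about a minute on one CPU. Convergence
is assessed with rank-normalized split R-hat (arviz) and the accepted-fit
threshold is max R-hat < 1.05. Subject-level point summaries, where
exported, use the posterior mode (KDE argmax on the constrained scale).

## Model comparison

Pointwise units are observed subject × trial terms. Per-unit expected log
predictive densities come from PSIS leave-one-out (arviz's Pareto-smoothed
importance weights; Pareto-k values are exposed for diagnosis). Two
combination rules are computed: Bayesian stacking — the concave mixture
score maximized over the simplex with SLSQP from a uniform start, so
exact ties resolve to uniform weights — and pseudo-BMA+, a
Bayesian-bootstrap (Dirichlet(1), 1000 replicates, seeded) softmax of
weighted elpd totals. Adding a constant to every entry of every model's
matrix leaves both weight sets unchanged. Whether units should be
subject × trial or whole subjects is not determined by the problem; the
per-trial choice maximizes the information entering the PSIS smoothing and
is configurable upstream by aggregating the matrices.

## Condition contrasts

Pairwise session differences of group-level parameters are standardized
per draw on the unconstrained scale: δ = (μ₂ − μ₁)/τ. τ is the pooled
subject-level SD of the two cells (root mean square of the cells' implied
variances, each the sum of its design columns' σ²); per-cell alternatives
are available. The Savage–Dickey Bayes factor divides the prior density at
δ = 0 by the posterior density at 0, the latter estimated by Gaussian KDE
with Silverman bandwidth (a moment-matched normal approximation is
provided as a cross-check, and the two agree within ~10% near the mode).
The δ prior defaults to standard normal — an effect-size expectation of
order one on the standardized scale — and is an explicit argument
everywhere it enters, since the Bayes factor is sensitive to it. A
vanishing posterior density at 0 caps BF₁₀ at 10⁶ with a flag rather than
returning infinity. 95% credible intervals are highest-density intervals
(narrowest contiguous window over sorted draws); direction probability is
the fraction of positive draws.

The paired-t power routine iterates the exact noncentral-t power upward in
n; at d = 0.47, power 0.80, α = 0.05 it returns 38.

## Synthetic cohort: what it emulates, and what not

The generator reproduces the design: `n_subjects = 40` by default, three
sessions × two feedback blocks × 28 trials, schedules regenerated per
session (a `yoke_schedules` flag reuses one schedule everywhere, since the
original counterbalancing leaves both readings open). Individual
parameters are drawn once per subject from the column-level group normals
and held fixed across that subject's cells through the design-matrix sum,
exactly mirroring the fitted model. Default generating values (probit
scale) put the average subject at η_rew ≈ 0.50, η_nrew ≈ 0.31 — positive
feedback weighted more than negative, as reliably observed in this task
family — and β ≈ 1.5 of U_β = 10, inside the 0.5–2 range such experiments
report; isolation difference columns add a small positive shift (+0.2,
with +0.3 for the media session's β social column), matching the direction
and rough magnitude of the reported condition effects. Baseline columns
get subject SD 0.4 and difference columns 0.2.

The cohort stores its schedules and per-trial uniforms, so stored
ground-truth parameters replay the simulated choices exactly.

What the generator does **not** emulate: response times and the 1-s
deadline (missing trials are representable but not generated), session
order effects, stimulus-pair idiosyncrasies, subject dropout, or any
departure of real participants from the fictitious-update model. Passing
recovery and selection tests on this cohort therefore shows the estimator
and comparison machinery are correct and well calibrated under the model,
not that the model is true of any real population.

## Validation suite

- **Posterior predictive checks** re-simulate every subject-cell block on
  fresh schedules for each of `n_rep` posterior draws and compare
  accuracy-by-phase summaries; self-consistency (simulating from known
  parameters and checking those parameters' predictive intervals) covers
  ≥ 90% of cells.
- **Parameter recovery** simulates a cohort from known group values,
  refits, and requires every group-level mean and SD to fall inside its
  95% HDI; at the reduced scale (15 subjects, 2 × (500+500)) all 36
  group-level values are recovered.
- **Grid simulation**: 60 × 60 cells over η ∈ [0, 1], β ∈ [0, 20], 200
  independent 28-trial blocks per cell with single-learning-rate
  fictitious agents (the virtual participant uses one η for both outcome
  signs), accuracy = fraction of better-option choices, Gaussian smoothing
  with std 2 grid cells in reflect mode (which preserves the surface mean
  to well under 0.01), optimum = mean of the ten highest smoothed cells.
  The original procedure ran one trajectory per cell over six blocks and
  relied on smoothing; 200 replicates per cell reach the same smoothed
  surface with less noise at negligible cost. The optimum lands at high η
  (≈ 0.8) and β ≈ 14, comfortably above the β > 3 qualitative boundary;
  the β = 0 edge sits at chance.

## Problem sizes and determinism

Every operation is a pure function of its inputs including an explicit
seed; chain and target seeds are spawned from a root `SeedSequence`. The
test suite and the acceptance script use reduced sizes chosen as the
smallest at which each property is cleanly decidable: 8–15 subjects for
fits, 2 chains × (300–500 + 300–500) iterations, 200 grid replicates per
cell, 14 000 schedule trials for the calibration estimate.

## Known limitations

- The NUTS implementation is single-threaded and diagonal-metric only;
  strongly correlated posteriors would mix slower than with a dense
  metric.
- EWA-family fits can place mass near ρ ≈ 1, φ ≈ 1 where values grow and
  the likelihood surface flattens; bounds are enforced by the link, not by
  reparameterization.
- The Savage–Dickey KDE estimate degrades when the posterior places
  almost no mass near 0 (the capped-BF path); the normal-approximation
  cross-check should be consulted there.
- Behavioral indices assume two options and schedule-derived phase
  annotations; they do not infer reversals from behavior.
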
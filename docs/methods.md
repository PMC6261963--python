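# Methods

This note documents the models, the sampler, the synthetic-data generator
and the numerical choices made in `placebo_rl`, in the package's own words.

## Task model

A session presents one of three symbol pairs per trial; within each pair one
symbol is rewarded with higher probability. Built-in designs:

| design | contingencies | blocks | trials |
|---|---|---|---|
| `task1_default`, `task3_default` | 80/20, 70/30, 60/40 | 4 | 240 |
| `task2_placebo` (easier) | 90/10, 90/10, 80/20 | 2 | 120 |
| `task2_nocebo` (harder) | 60/40, 60/40, 55/45 | 2 | 120 |

Every pair appears 20 times per block; the better symbol is on the left in
exactly half of those occurrences; the within-block order is a uniformly
random (unconstrained) permutation given the seed. Trial timing (0.3 s
fixation, 1.7 s response deadline, 0.5 s highlight and feedback) is stored
as design metadata only. Feedback is an independent Bernoulli draw at choice
time. Rewards are coded r ∈ {0, 1} (gain = 1, loss/no reward = 0) — a
deliberate convention consistent with Q₀ = 0 and learning rates in [0, 1],
which keeps every value estimate inside [0, 1].

Group schedules follow the five-arm, two-day flow: the NHG runs the default
task on both days; the four manipulated arms add their manipulated session
after the default task on day 1.

## Agent and likelihood

The agent updates only the chosen symbol's value with the gain rate α_G for
positive prediction errors and the loss rate α_L for negative ones (a zero
prediction error changes nothing; implementing the positive/negative parts
with strict inequalities avoids double-counting the measure-zero tie).
Choices are softmax in the value difference with noise parameter β > 0,
evaluated as a logistic of (Q_b − Q_a)/β for numerical stability.

The fitted likelihood replays each subject-session deterministically from
the recorded choices and rewards. Each task session is a fresh *episode*
with Q re-initialised at zero: tasks use disjoint stimulus sets and the
model estimates per-day parameters, so no value carries across sessions or
nights. Missed trials (no response, hence no feedback) are excluded from
the likelihood and do not advance Q. The manipulated day-1 session enters
the likelihood with that subject's day-1 parameters.

## Hierarchy, transforms and priors

Subject-level parameters live on transformed scales: probit(α_G), probit(α_L)
(logit available via `link="logit"`; the probit form follows the model
equations, and the one place the source material labels these effects
"logit-scale" is treated as a caption inconsistency), and log(β). Day-1
values are Normal(μ_θ, σ_θ); day-2 values add a common day shift b_θ plus a
group-specific shift b_θ,group (zero for the NHG). All 15 shift effects —
3 day effects + 12 group effects — share a Normal(0, σ_b) shrinkage prior
by default (`shrink_common_day_effects=False` restricts the shrinkage to
the 12 group effects and gives the day effects an independent Normal(0, 1)
prior).

Hyperpriors (defaults of `PriorConfig`): μ_α ~ Normal(−0.5, 0.6),
μ_β ~ Normal(−1.5, 0.8), σ_α ~ HalfCauchy(0.01), σ_β ~ HalfNormal(0.3),
σ_b ~ HalfNormal(1). The HalfCauchy scale of 0.01 is unusually small but is
implemented exactly as specified (and is configurable); its heavy tail
still lets the data move σ_α upward. σ_b is given positive support as a
half-normal since a scale cannot be negative. The implied subject-level
prior puts most learning-rate mass below 0.5 and most β mass below 2
(β = 2 already implies near-chance choice), which the prior-predictive test
checks.

The model ladder: `single_alpha` (one α and one β per subject, shared across
days), `day_group` (single learning rate, parameters vary by day with
group-specific day-2 shifts), `full` (separate α_G/α_L, everything varies
by day). For a cohort containing all five groups the full model has 6
hyperparameters, 15 shrunk effects, σ_b, and 3 parameters per subject-day.

## Posterior sampling

No probabilistic-programming framework with gradient-based samplers is part
of this package's dependency set, so sampling is provided by two
package-authored backends behind one `SamplerConfig`:

**Blocked Metropolis-within-Gibbs (default, `sampler="gibbs"`).** The
posterior factorises: given the hyperparameters the subject-day blocks are
mutually independent, and given the subject-day values the location
parameters have exactly Gaussian conditionals. One sweep performs
(1) parallel one-parameter-at-a-time random-walk MH updates of every
subject-day value using batched per-episode likelihood kernels (numba),
(2) joint *translation* moves that shift a location parameter (μ_θ, b_θ, or
b_θ,group) together with the subject values it locates, holding the
standardised residuals fixed, (3) joint *rescaling* moves that multiply
σ_θ and its residuals together (the subject-prior change cancels against
the transform Jacobian), (4) exact Gibbs draws for μ_θ and every shift
effect, and (5) adaptive 1-D MH for log σ_θ and log σ_b. Proposal scales
adapt toward acceptance targets of 0.44 during warm-up only and are frozen
afterwards, so the retained draws come from a fixed transition kernel.
Chains are genuinely independent (the whole state is vectorised across
chains) with overdispersed random initialisation; the default configuration
is 8 chains × 1000 warm-up sweeps with 1000 retained draws per chain (8000
total). The translation and rescaling moves are what make the location- and
scale-funnel directions mix; without them the integrated autocorrelation
time of the scale parameters is an order of magnitude longer.

**Differential-evolution ensemble (`sampler="ensemble"`).** A thin driver
around `emcee` with DE and snooker moves, walkers grouped into reporting
chains. It is retained as an independent cross-check of the Gibbs sampler
(their posteriors agree on small problems) and is the backend for the
behavioural regressions, whose dense design matrices lack the conditional
structure the Gibbs sweep exploits.

The hierarchical model uses the *centred* parameterisation by default: with
hundreds of trials per subject-day the latent parameters are strongly
likelihood-identified, which is the regime where centred geometry mixes
better. The non-centred form is available (`parameterization="noncentered"`)
and defines the same posterior (tested via the Jacobian identity). A
caution that follows from centred geometry: the density is unbounded along
σ → 0 with residuals exactly zero, so mode-seeking initialisation is not
used by default.

Diagnostics are rank-normalised split Gelman–Rubin statistics and
autocorrelation-based effective sample sizes per parameter; constant chains
define R̂ = 1. Any R̂ > 1.1 raises a `ConvergenceWarning` — never a silent
pass. Divergence counts are reported as zero by construction: neither
backend is a Hamiltonian method, so the field exists only to keep the
diagnostics container uniform.

## Model comparison

The pointwise log-likelihood matrix evaluates every retained draw on every
trial (one trial = one leave-one-out unit, matching the likelihood's
factorisation; `groups=` enables leave-one-subject-out). PSIS-LOO uses
Pareto-smoothed self-normalised importance weights (smoothing via arviz's
`psislw`), with observations above the standard Pareto-k threshold of 0.7
counted and warned about. Below 25 draws the generalised-Pareto tail fit is
undefined and raw self-normalised weights are used instead (warned). LOOIC
= −2·elpd_loo; |ΔLOOIC| > 10 is flagged "strong". In the no-variance limit
LOOIC reduces to the deviance, which the tests assert exactly.

## Behavioural and subjective-report regressions

Accuracy (answered trials of the default-contingency sessions, logit link)
and reaction time (milliseconds, identity link; RTs are standardised
internally and coefficients reported back in ms) are modelled with
treatment-coded fixed effects — trial (z-scored over included rows), pair
(baseline AB), day (baseline day 1), group (baseline NHG), and the
trial × pair, trial × day, day × group interactions — plus correlated
subject-level random effects (intercept, trial, pair) parameterised by an
unconstrained Cholesky factor (log-diagonals half-normal, off-diagonals
normal). Priors on fixed effects are Normal(0, 2.5) on the standardised
scale; the source analyses state no priors, so these weakly-informative
defaults are the package's own. No RT trimming is applied by default.
Group contrasts δ are per-draw differences of day × group coefficients.

Subjective reports (decline / neutral / improve, one response per question)
use a multinomial-logit regression with factors task-manipulation
(placebo-type vs nocebo-type arm), question (expected vs perceived) and
group (experimental vs control), plus group × question and
group × manipulation interactions; the reference category is "neutral", and
all reported quantities are implied per-cell probability triples, which are
exactly invariant to the reference choice (tested by reparameterisation).
The factor structure has 6 terms for 8 cells, so cell probabilities are
deliberately smoothed rather than saturated.

## Synthetic-data generator

`CohortSpec`/`simulate_cohort` generate cohorts exactly under the fitted
hierarchy: subject values drawn on the transformed scales, day-2 shifts
applied there, behaviour simulated through the group schedules. Defaults
are the study's conditions (16 subjects per group, the built-in designs).
Two generator-only switches exist so that data can be generated *from* the
simpler ladder variants: `single_alpha` (one shared learning-rate draw) and
`share_days` (day-2 parameters identical to day 1).

What the generator does **not** emulate: reaction times are invented
plumbing (lognormal around exp(6.7) ≈ 810 ms with configurable shifts,
capped at the deadline) because the learning model says nothing about RTs;
subjective responses are drawn from user-supplied per-group categorical
probabilities; there are no missed trials, no fatigue or drift within
sessions, and no violation of the model's own assumptions. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the model, not robustness to model misspecification in
real data.

## Validation studies and problem sizes

- **Performance map**: Monte-Carlo mean accuracy over a 2-D parameter grid
  on a fixed seeded schedule of the default session; 200 replicate agents
  per cell by default (a cost/precision trade-off). Its qualitative
  geometry: zero learning or β ≥ 10³ give chance performance; at fixed
  moderate learning rates accuracy peaks at a moderate β (greedy and noisy
  extremes both lose).
- **Parameter recovery**: simulate → fit → score bias, RMSE, 95%-HDI
  coverage of group-level means and shift effects, and Spearman correlation
  between true and estimated subject parameters. The test-suite
  configuration uses two replicates of a 16-subject, two-group cohort with
  240-trial days and a 4-chain reduced draw budget — small enough to run at
  a desk, large enough that shrinkage does not dominate the intervals.
- **Model recovery**: cohorts generated from the full model with well
  separated learning rates (α_G ≈ 0.7, α_L ≈ 0.2) make LOOIC prefer the
  dual-rate model strongly (ΔLOOIC ≫ 10); cohorts from the single-rate
  model yield no strong preference.
- **Convergence study** (`reduced_study_spec`): 4 NHG + 4 placebo subjects,
  two-block (120-trial) default sessions, realistic hyperparameters
  (α_G ≈ 0.38, α_L ≈ 0.21, β ≈ 0.30 at the group medians) and a day-2
  gain/loss shift of ±0.2–0.3; fit with 8 chains, 2000 warm-up sweeps,
  1000 retained draws per chain. This is the configuration
  `scripts/acceptance.py` re-runs from scratch.

## Known limitations

- The samplers are random-walk based within blocks; posteriors with very
  weak subject-level identification (few trials and large β) mix more
  slowly than gradient-based HMC would.
- HDIs use the narrowest-interval construction and assume unimodality.
- The likelihood treats the randomisation as unconstrained permutations; if
  the original stimulus software constrained immediate pair repetitions,
  exact sequence statistics would differ (this does not affect inference
  given recorded sequences).
- Per-trial PSIS-LOO on hierarchical RL fits often shows many moderate
  Pareto-k values at reduced draw budgets; the comparison is still
  informative at the ΔLOOIC ≫ 10 scale used here, and high-k counts are
  always reported.
- Reproducing the original study's real-data coefficient tables requires
  the deposited trial data; the column-mapped reader supports loading such
  tables, but no such comparison is bundled.
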
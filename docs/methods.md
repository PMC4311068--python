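# Methods

## Task environment

The environment reproduces a two-session probabilistic reversal-learning
protocol: 200 trials (100 per session), three block types assigning reward
probability (left, right) = (0.8, 0.2), (0.2, 0.8) or (0.5, 0.5), feedback
shown for 1 s, inter-trial intervals drawn uniformly from 1.0–6.5 s (the
protocol states the range; the uniform law is our choice). A block ends as
soon as the agent has completed at least 10 trials of it with at least 70%
of them "correct", or unconditionally after 16 trials; the next block type
is drawn uniformly from the two other types (the schedule is specified only
as "unpredictable"). The first feedback onset is fixed at 2 s; simulated
agents respond instantly, since reaction times influence nothing downstream.

"Correct" needs two definitions. For the *switching criterion*, which must
operate in every block, a response counts as correct if it selects the
higher-probability action in asymmetric blocks and if it is rewarded in
50/50 blocks (where no better option exists); a feedback-only rule is
available via `TaskConfig(criterion_rule="rewarded")`. For the *behavioral
accuracy summary*, accuracy is the fraction of asymmetric-block trials on
which the 0.8-probability action was chosen; 50/50 trials are excluded
because accuracy is undefined there. Simulated at the population-median
parameters below, 1,000 agents average ≈ 70% correct by this convention —
the quantity `scripts/acceptance.py` recomputes.

Sessions are separate scanner runs: the block schedule restarts at the
session boundary, but the learner's values carry over (subjects are not
told about reversals or session structure); `carry_values=False` resets
them. Missed trials are not simulated; the event-table reader drops
rows whose action is not L/R, because the choice likelihood is defined only
over made responses.

## Observation model and likelihood

The learner is a two-armed Rescorla–Wagner model: softmax choice over
action values, delta-rule update of the chosen value only (no decay or
forgetting of the unchosen action), effective reinforcement +β_rew after
reward and −β_pun after loss. Initial values are Q₀ = (0, 0), the neutral
convention; it makes the β = 0 likelihood exactly n·log ½, which the tests
pin. The log-likelihood of a choice sequence sums log softmax probabilities
of the chosen actions along the value recursion. Its gradient with respect
to θ = (logit ε, log β_rew, log β_pun) is computed exactly by propagating
dQ/dθ through the recursion — no finite differences in the inner loop —
and is verified against numerical differentiation in the tests. Softmax
terms use max-subtraction / log1p forms throughout, and the unconstrained
parameters are clamped to |θ| ≤ 50 inside the kernel so optimizer line
searches cannot overflow.

## Hierarchical estimation

Per-subject parameters are maximum-a-posteriori estimates in θ-space under
a Gaussian population prior N(μ, Σ); the prior is estimated by
expectation–maximization with a Laplace approximation:

- E-step: L-BFGS-B maximization of log p(A_i|θ) + log N(θ; μ, Σ) per
  subject (bounds ±25, gradient tolerance 1e-6; 5 starts in the first
  iteration — prior mean plus prior draws, since RL likelihoods can be
  multimodal — then warm starts from the previous optimum plus the prior
  mean). The posterior covariance is approximated by the inverse Hessian of
  the negative log posterior (central differences of the analytic gradient,
  floored to positive definite).
- M-step: μ ← mean of the MAP estimates; Σ ← mean of [outer deviation +
  Laplace covariance].
- Initialization μ = 0, Σ = 6.25·I (broad, to avoid early over-shrinkage);
  stopping when every entry of μ and Σ changes by less than 1e-3, or after
  100 iterations. The summed per-subject log posterior is recorded each
  iteration; it should be non-decreasing up to Laplace noise and the tests
  flag drops larger than 1.0.

**Why the population covariance is diagonal by default.** The choice
likelihood is almost invariant under (β_rew, β_pun) → (β_rew + c, β_pun − c):
the softmax depends only on value differences, and shifting both
sensitivities shifts the whole value trajectory once the influence of
Q₀ = 0 has washed out. With values carried across sessions there is a
single Q₀ anchor per subject, so the split between the two sensitivities is
only weakly identified — essentially their sum is learned from the data.
A full-covariance M-step inflates Σ along this ridge, the per-subject MAP
estimates then slide freely along it, and between-subject ordering of
β_rew degrades badly (on a 50 × 200 recovery run, rank correlation 0.64
full vs 0.87 diagonal, against a ceiling of 0.88 when fitting under the
true generating prior). A diagonal Σ regularizes the ridge without touching
the well-identified directions; `diagonal=False` restores the full update.
The same ridge explains why punishment-sensitivity recovery is poor in this
design no matter the estimator, and why a bounded grid search under a flat
prior can drift arbitrarily — oracle-equivalence tests therefore use the
broad (Σ = 6.25·I) prior.

The reported per-subject log-likelihood is the data term at θ_MAP (not the
posterior value). The quartile summary labels the punishment column
"-beta_pun" after the sign with which it enters the reinforcement, but
prints the positive magnitude, and prints |LL|.

## PE regressor and single-voxel GLM

Feedback events are sticks on a microtime grid (TR 2.3 s, 310 volumes per
session, 16 microtime bins per TR), with a parallel stick train carrying
the trial PE values, mean-centered per session — the usual parametric-
modulation convention, which also decorrelates the modulator from the onset
regressor. Both trains are convolved with the canonical double-gamma HRF
(response peak 6 s, undershoot 16 s, ratio 1/6, 32-s support) and decimated
to the TR grid. The HRF is normalized to unit peak, so GLM betas are in PE
units. The whole fMRI stage is deliberately a one-voxel abstraction: no
volumes, smoothing, motion regressors (optional nuisance columns are
accepted) or cluster statistics, because the group analysis consumes only
one scalar per subject — the OLS coefficient of the PE-modulated regressor,
sessions fitted separately and betas averaged. The forward model adds AR(1)
Gaussian noise (marginal SD fixed, default coefficient 0.3) on top of the
scaled PE regressor plus a baseline of 100. OLS ignores the
autocorrelation — betas stay unbiased — and the t-statistic is flagged
naive (`naive_t=True`); the distribution-level t checks in the tests
therefore use white noise.

## Moderation statistics

"Stepwise" is implemented as explicit two-step hierarchical entry — main
effects, then the constructed interaction — not automated p-in/p-out
selection. SLES is coded either by median split (at-or-below median → 1,
above → 2; ties go low, configurable) or as a continuous z-score, and the
interaction multiplies the code with the raw, uncentered PE beta (a
centered variant exists; centering changes the main-effect coefficients'
meaning but not the interaction test). Standardized coefficients are
b·sd(x)/sd(y) on the fitted columns. The F-change statistic is computed
from the R² form with q = 1 added term and n − k − 1 residual degrees of
freedom; the tests assert its algebraic identity with the partial-F of the
nested comparison to 1e-10. Influence is screened with Cook's distance
(flag at ≥ 1) and standardized residuals (flag at |z| ≥ 3); flagged points
are reported and never dropped. Age can enter both steps as a covariate.

## Synthetic cohorts

The generator emulates the study conditions: 16 subjects by default; RW
parameters drawn from a Gaussian in θ-space with μ = (logit 0.62, log 2.73,
log 0.84) — medians commute with monotone transforms, so the natural-space
medians land on the cohort medians being emulated — and diagonal SDs
(1.196, 0.699, 0.437) derived once from the reported quartiles via
σ = IQR/1.349. SLES counts are a rounded normal (mean 16.31, SD 4.59)
truncated to [0, 42]. The BOLD scale of subject i is s₀ + s₁·z(SLES) +
noise with s₁ = 0.3 > 0 (the positive stress–PE-signal association;
s₁ = 0 available for null testing), and fluid IQ is
0.60 + 0.5·scale + 0.05·z + b_int·scale·z + N(0, 0.35), i.e. a planted
moderation with almost no direct SLES–IQ effect. Ages are uniform 22–61 and
independent of everything.

Effect sizes the source text does not identify were calibrated **once**
(`scripts/calibrate_cohort.py`) and frozen: b_int = 0.8 and BOLD-scale
noise 0.4 give the qualitative high-stress ≫ low-stress subgroup-R²
pattern at n = 16 and interaction-test power 0.882 for the continuous-z
coding (2,000 replicates, calibration seed 987654, frozen as
`CALIBRATED_INTERACTION_POWER`). The median-split coding caps near 0.47
power regardless of effect size — the dichotomization cost that motivates
the continuous variant — so power is calibrated and tested on the
continuous coding. Synthetic BOLD noise SD defaults to 2.0, at which the
per-subject beta standard error is ≈ 0.07 and planted scales on a
{0, 0.5, 1, 2} grid are recovered in order essentially always.

Regression-level operating-characteristic simulations (type-I error, power)
use the generator's covariate-only mode, in which the true BOLD scale
stands in for the measured beta; this keeps 2,000-replicate simulations to
seconds and is conservative in neither direction at the default GLM noise
(beta measurement error ≈ 0.07 against a scale SD of 0.5). The full
simulate → fit → GLM → regression path is exercised by
`stressrl.cohort.end_to_end` and its tests at n = 16-scale cohorts.

What the generator does **not** emulate: scanner drift and motion (noise is
AR(1) only), missed responses, age structure in any covariate, the
item-level neuropsychological battery behind the fluid-IQ score, and
voxelwise spatial statistics. Passing tests therefore validate the
computational machinery and its statistical calibration on data satisfying
the model's assumptions — not the robustness of the original findings to
real-data violations of them.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen as reasonable defaults
for a laptop: 1,000 agents for posterior-predictive behavior, 50 × 200
trials for hierarchical recovery, 100/1,000 seeds for the GLM grid and
null-t checks, 2,000/1,000 replicates for type-I error and power. All
randomness flows from explicit `numpy.random.Generator` seeds; identical
seeds give byte-identical datasets and results.

## Known limitations

- The β_rew/β_pun split is weakly identified by design of the task (one
  Q₀ anchor per subject); punishment-sensitivity estimates should not be
  interpreted individually.
- EM convergence in μ/Σ can be slow on small cohorts (the objective trace
  keeps creeping); results objects expose `converged` and the trace so
  callers can judge.
- GLM t-statistics are naive under AR(1) noise; only betas are carried to
  the group level, so group inferences are unaffected.
- The one-voxel abstraction cannot reproduce spatial statistics (peak
  coordinates, FWE-corrected cluster p-values) and does not try to.
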
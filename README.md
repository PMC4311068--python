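# stressrl

Does chronic life stress change how strongly a basic neural learning signal
relates to fluid intelligence? This package re-implements, as tested and
reusable Python, the computational analysis behind that question: a
probabilistic reversal-learning task, a Rescorla–Wagner (RW) learner fitted
hierarchically across subjects, a prediction-error (PE) fMRI regressor and
single-voxel GLM, and a moderation regression in which a stressful-life-event
count (SLES) moderates the slope of fluid IQ on the per-subject "BOLD PE
signal". Because the original subject-level data are not public, the package
ships a synthetic-cohort generator with the same statistical structure, so
every stage — simulation, fitting, regressor construction, group statistics
— is exercisable and testable end to end.

It is aimed at computational-psychiatry and decision-neuroscience
researchers who want a desk-scale, fully seeded reference implementation of
this analysis style (hierarchical empirical-Bayes RL fitting plus
moderated-regression group statistics).

## The model

Choices in the two-session, 200-trial reversal task (blocks of 80/20, 20/80
and 50/50 reward probability, switching covertly once performance reaches
criterion) are modeled by a delta-rule learner with softmax choice:

    p(a | Q_t)      = exp(Q_t(a)) / Σ_a' exp(Q_t(a'))
    Q_t(a_t)        = Q_{t-1}(a_t) + ε · PE_t
    PE_t            = R_t − Q_{t-1}(a_t),   R_t = +β_rew (reward) | −β_pun (loss)

Parameters are estimated per subject as MAP values in the unconstrained
space θ = (logit ε, log β_rew, log β_pun) under a Gaussian population prior
N(μ, Σ) whose parameters are set by expectation–maximization over the whole
cohort (a Laplace-approximation random-effects scheme). The trial-wise PE
sequence at the MAP estimate, placed as a parametrically modulated stick
function at feedback onsets and convolved with the canonical double-gamma
HRF, yields a per-subject GLM coefficient — the BOLD PE signal β_PE.
Group-level inference is a two-step hierarchical regression

    step 1:  fluidIQ ~ β_PE + SLES
    step 2:  fluidIQ ~ β_PE + SLES + β_PE × SLES

with SLES coded by median split or as a continuous z-score, judged by the
F-change test on R², with Cook's-distance/standardized-residual screening.

## Worked example

```python
from stressrl import (CohortSpec, HierarchicalRWModel, ModerationModel,
                      generate_cohort, fmri)

data = generate_cohort(CohortSpec(), seed=42)          # 16 synthetic subjects
fit = HierarchicalRWModel(data.events).fit(seed=42, max_iter=30)
print(fit.summary())

traces = fit.pe_traces()                               # PEs at the MAP fits
pe_beta = [
    fmri.fit_glm(
        data.bold[sid],
        fmri.build_session_designs(data.events[sid], tr.pe,
                                   data.spec.scan_protocol),
    ).beta_pe
    for sid, tr in zip(data.events, traces)
]
res = ModerationModel(data.cohort.assign(pe_beta=pe_beta),
                      coding="continuous_z").fit()
print(res.summary())
```

which prints

```
Hierarchical Rescorla-Wagner fit: 16 subjects, EM iterations=30, converged=False
prior mu = [ 0.323  1.205 -0.095]
prior sigma diag = [0.588 0.248 0.612]

                 beta_rew  -beta_pun    LL  epsilon
25th percentile      2.42       0.70 53.60     0.43
Median               3.40       0.91 82.42     0.57
75th percentile      4.73       1.10 96.41     0.70

Moderation regression (coding=continuous_z, n=16)
step 1  R^2 = 0.856
step 2  R^2 = 0.970   F-change(1, 12) = 45.01, p = 0.0000

full model (standardized beta, t, p):
  pe_beta          beta =   0.12   T =  1.40   p = 0.1855
  sles_code        beta =   0.08   T =  0.62   p = 0.5452
  pe_x_sles        beta =   0.82   T =  6.71   p = 0.0000
influence: max Cook's D = 0.442, max |z| = 1.66, 0 flagged
```

The quartile table summarizes the cohort's fitted reward/punishment
sensitivities, log-likelihood magnitudes and learning rates (the population
medians used by the generator are ε ≈ 0.62, β_rew ≈ 2.73, β_pun ≈ 0.84).
The moderation summary shows the planted pattern: little direct SLES–IQ
association, and a strong PE-signal × stress interaction that lifts R² from
step 1 to step 2 (significant F-change). `res.plot_subgroups(cohort_table)`
draws the corresponding median-split scatter with per-subgroup fits.

The same pipeline is scriptable from the shell:

```bash
stressrl generate --seed 7 --out dataset/
stressrl fit --events dataset/events --out fits/ --seed 1 --em
stressrl stats --cohort dataset/cohort.csv --coding continuous --out results/
```

## Layout

- `stressrl.task` — reversal-task environment, block-switch rule, event TSVs
- `stressrl.rw` — RW/softmax likelihood, exact gradient, PE traces, agents
- `stressrl.hierarchical` — MAP fitting, Laplace EM, model/results classes
- `stressrl.fmri` — canonical HRF, PE design matrices, BOLD forward model, GLM
- `stressrl.moderation` — correlations, median split, moderation regression
- `stressrl.cohort` — synthetic cohorts with ground truth; end-to-end runner

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
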
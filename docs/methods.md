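# Methods

## The response model

US-expectancy ratings are percentages in [0, 100] with a heavy atom at 0:
once a participant is sure no spider will follow the cue, they answer 0%
exactly, while intermediate beliefs produce graded responses. The package
models the transformed rating `y = raw / 101` (so `y < 1` always) with a
zero-inflated ("ordered") beta distribution driven by one logit-scale linear
predictor ζ:

    θ = σ(ζ − γ)            probability of a non-zero rating
    μ = σ(ζ)                mean of the continuous branch
    y = 0                   with probability 1 − θ
    y ~ Beta(μτ, (1−μ)τ)    otherwise, τ = e^φ

σ is the logistic function. Because the same ζ governs both the zero
probability and the continuous mean, the two parts are *ordered*: as
expectancy declines across extinction trials, the continuous ratings drift
down and the zero atom swells, with a single threshold γ controlling where
the zero mass sits relative to the continuous scale. One common precision φ
is shared by all observations. There is no one-inflation component: after
the ÷101 transform the maximum attainable value is 100/101, so the upper
boundary is never observed.

The linear predictor is a mixed-effects design,

    ζ_it = Xβ + u_i0 + u_i1·trial_t + w_t,

with a bivariate participant deviation (intercept, trial slope; SDs σ_0,
σ_1, correlation ρ) and a crossed per-trial intercept w_t. Fixed-effect
designs cover the pipeline's named models: `acquisition`
(trial + CS type + interaction, CS effects-coded −0.5/+0.5), `baseline`
(trial only, CS+ extinction trials), `moderated` (baseline + z-scored
questionnaire moderator + trial × moderator), and `linear` (the baseline
design under a normal likelihood — the model-comparison foil). Trials are
coded 0-based within phase, uncentered, so the intercept is the expected
logit-scale rating on the first modeled trial; the random slope uses the
same covariate.

### Rating scales in fits

When a table carries exact continuous unit-interval ratings (column
`rating_unit`, as produced by the simulator), fits use them directly.
Integer percent ratings from CSV are divided by 101. This distinction
matters: rounding continuous ratings to integer percents censors the top of
the scale (every value above 100.5/101 collapses onto 100/101), which
measurably biases φ and the random-effect SDs upward/downward in
parameter-recovery experiments. Boundary-adjacent continuous values are
clamped into [1e−12, 1 − 1e−12] before the Beta density is evaluated; no
realizable ÷101 value is affected.

## Priors

The analysis is Bayesian with weakly informative priors chosen on the
logit/unit scales (all configurable through `PriorSet`):

| parameter | prior | rationale |
|---|---|---|
| intercept | Normal(0, 5) | covers the whole plausible logit range |
| other coefficients | Normal(0, 2.5) | weakly informative on logit scale |
| threshold γ | Normal(0, 2.5) | same scale as ζ |
| log-precision φ | Normal(0, 2) | τ between ~0.02 and ~55 at ±2 SD |
| random-effect SDs | half-Normal(0, 2.5) | standard weakly informative scale prior |
| intercept–slope correlation | LKJ(2) | mild shrinkage toward 0 |
| residual SD (linear family) | half-Normal(0, 1) | unit-interval response |

Prior choices move Bayes-factor magnitudes by construction, so marginal-
likelihood comparisons under these defaults are decision-grade (orders of
magnitude) rather than numerically portable across prior specifications.

## Sampling

No general-purpose MCMC backend ships with the package's environment
requirements, so inference uses a self-contained Hamiltonian Monte Carlo
sampler (`extbeta._hmc`): static trajectories with ±25% length jitter,
dual-averaging step-size adaptation toward 85% acceptance, and a diagonal
mass matrix estimated from the middle half of warmup. All parameters are
unconstrained before sampling — log SDs, tanh-transformed correlation, and
*non-centered* random effects (standard-normal innovations scaled inside
the model), which keeps the posterior geometry close to unit scale and
avoids the funnel pathologies of centered hierarchical parameterizations.
Gradients of the joint density are analytic (digamma terms for the Beta
branch) and verified against central differences in the test suite.
Defaults: 4 chains, 1000 warmup + 1000 retained draws, explicit seed.
Diagnostics come from arviz: fitting raises when split-R̂ exceeds 1.05 on
any fixed effect and warns on divergences or effective sample sizes
below 100. Per-observation log-likelihoods and the unconstrained draw
matrix are retained on every fit; they feed PSIS-LOO and bridge sampling.

## Model comparison

- **Bayesian R²** uses the residual-based formulation
  `var(pred) / (var(pred) + var(y − pred))` per posterior draw, which is
  defined for non-normal families. Conditional R² includes the fitted
  random effects in the predictions (response scale: θ·μ for the ordered
  family, ζ for the linear family); marginal R² uses fixed effects only.
- **ELPD (PSIS-LOO)** via arviz on the retained log-likelihood matrix;
  model differences are computed pointwise with a paired standard error.
  A brute-force exact leave-one-out refit (`exact_loo`) serves as the
  oracle for small fixed-effects-only data sets.
- **Bayes factors** via iterative (Meng–Wong optimal) bridge sampling with
  a moment-matched multivariate-normal proposal on the unconstrained
  scale; half the posterior draws fit the proposal, the other half enter
  the estimator. The error estimate is a split-half spread. The estimator
  is validated against a closed-form conjugate normal marginal likelihood.
- **Posterior predictive overlays** replicate the full data set from
  randomly chosen posterior draws, conditioning on the fitted random
  effects (the observed cohort), and overlay Gaussian-KDE densities; the
  kernel smoothing pushes some empirical mass outside [0, 1], which is a
  property of the display, not the model. Linear-family replicates can
  genuinely leave the unit interval — that contrast is the point of the
  display.

## The synthetic cohort generator

`synthetic_data` emulates the VR fear-conditioning paradigm exactly:
pre-acquisition 2+2 unreinforced presentations; acquisition 10+10 with the
first trial a reinforced CS+, 6/10 CS+ reinforcement (distinct spider paths
1–6, no repetition), and no more than two same-CS trials in a row
(rejection sampling over uniform interleavings, hence uniform over valid
sequences); one reinforced reacquisition CS+ trial on path 5; extinction
20+20 unreinforced under the same run rule. Ratings are drawn from the
ordered beta generative model above with crossed random effects.

Default generating values define the package's reference extinction
scenario: intercept 1.88, trial slope −0.24, participant SDs 1.04 / 0.19
with correlation −0.49, trial-intercept SD 0.20, threshold γ = −2.35, and
log-precision φ = log 5. Two of these deserve comment:

- **φ = log 5** yields realistic dispersion of continuous ratings
  (continuous-branch SD ≈ 0.14 at μ = 0.5).
- **γ = −2.35** places almost no probability on exact-zero answers while
  expectancies are high (trial-0 mean rating ≈ 0.85) and lets the zero
  fraction grow steadily as ζ declines across extinction. A *positive*
  threshold of the same magnitude would instead imply a majority of 0%
  answers on the very first extinction trial and a trial-0 mean of 0.33 —
  not what extinction trajectories look like. Note that cutpoint sign
  conventions differ across ordered-beta implementations, so a threshold
  printed as 2.35 elsewhere can denote the same model as γ = −2.35 here;
  always check the implied zero fraction rather than the sign.

Moderator scores default to a realistic IUS-12 score distribution for a
spider-fearful sample (mean 29.70, SD 7.28) and are z-scored across
participants before entering the model. Raw integer ratings are produced by round-half-up of
`unit × 101` for platform-determinate CSV output.

What the generator does **not** emulate: response-time structure,
sequential dependence beyond the trial random intercept, participant
dropout, anchoring or digit-preference in VAS responses, and any
correlation between questionnaire scores. Passing recovery and
model-selection tests on this generator therefore demonstrates internal
consistency of the estimation machinery under the stated generative model,
not robustness to the full messiness of real rating data.

## Power analysis

The target effect is a correlation r between the z-scored moderator and the
participant-level extinction slope. With the moderator standardized, the
interaction coefficient b = r·σ_slope combined with a residual slope SD of
σ_slope·√(1−r²) produces exactly that correlation while holding the
marginal slope variance fixed — so changing r changes the slope's
*composition*, not its total heterogeneity. Each replicate simulates a
cohort, fits the moderated ordered beta model, and rejects when the
one-sided 95% credible interval for the interaction excludes zero in the
hypothesized direction; fit failures are counted and reported separately.
Power carries a Wilson binomial interval. An effect stated as a
correlation does not uniquely determine a model coefficient, so this
mapping is the package's own declared, configurable choice.

## Problem sizes in the shipped checks

The test suite and the acceptance script scale the Monte-Carlo studies to
desk-scale sizes chosen once: 10 replicates of 40 participants × 20 CS+
extinction trials for recovery and model selection (2 chains, 500 + 500
draws); a 30-observation set for the exact-LOO oracle; 24 null replicates
at 30 participants × 10 trials for power calibration plus 12-replicate
arms for monotonicity; one 71-participant cohort for the study-sized fit
in the acceptance script. Calibration properties (interval coverage,
type-I rate of the one-sided rule) do not depend on these sizes; power
magnitudes of course do, and are reported together with their replicate
counts.

## Numerical choices and degenerate inputs

- `logistic` rejects non-finite input; it is exact to saturation (|z| ≈ 700).
- Joint-density evaluations bail out (−∞) when any unconstrained scalar
  exceeds 100 in magnitude, so runaway leapfrog trajectories are rejected
  as divergences instead of overflowing.
- The tanh-transformed correlation is clamped to ±(1 − 1e−9) to keep its
  Cholesky factor and the LKJ density finite.
- HMC iterations with Hamiltonian error beyond 1000 are flagged divergent
  and rejected.
- Paired tests reject fewer than 2 pairs and zero-variance differences
  (the degenerate d_z); the noncentral-t CI inversion falls back to the
  Johnson–Kotz normal approximation only where scipy's noncentral-t CDF
  underflows.
- Schedule generation is a pure function of (config, seed); an
  unsatisfiable configuration (e.g. more reinforced trials than distinct
  spider paths) is rejected at construction.

## Known limitations

- The HMC sampler is tuned for this model family; it is not a
  general-purpose replacement for adaptive tree-depth samplers, and very
  small effective sample sizes can occur for weakly identified variance
  components on small cohorts (the diagnostics surface this).
- Bridge-sampling marginal likelihoods in ~100-dimensional random-effect
  spaces carry Monte-Carlo error of a few log units; Bayes factors are
  decision-grade (orders of magnitude), not third-digit-grade.
- Coefficient estimates on real data depend on the prior specification;
  the shipped defaults are documented above and fully configurable.
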
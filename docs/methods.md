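# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limits of what the package's tests can
show. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and normalization

A study is a long table of (participant, arm, item, beep, response) with
one arm answering on a 7-point Likert scale (raw 1..7) and one on a 0–100
VAS. All analysis happens on the normalized unit interval — Likert
`(k−1)/6`, VAS `v/100` — which treats both scales as ratio-scaled; this is
an assumption, not a fact, but it is the only way to compare the arms on
common ground and matches how bounded-response models treat such data.
The beep grid is a fixed index 1..84 (6/day × 14 days); clock times are
not modeled. Missingness is an absent row, surfaced to the statistics as
NaN slots on the grid — never a sentinel value.

Inclusion requires ≥ 20 of 84 possible beeps (at ~0.15 within-person SD
this caps the standard error of a within-person mean near 0.035). Lagged
statistics additionally require ≥ 20 *valid pairs* — consecutive beeps
both observed — because a missing beep can neither predict nor be
predicted; participants are flagged, not silently dropped, so the lagged
analyses run on their own (smaller) eligible sample. Careless-response
screening generalizes "all items identical at every answered beep" to a
reproducible rule: flag when the fraction of completed beeps with zero
within-beep variance reaches a threshold (default 1.0). Flags are
reported, never auto-applied.

## Synthetic study generator

The generator produces the structure the analysis assumes, so every
downstream stage can be validated without restricted raw data:

- **Latent affect** `x[i,j,t] = m[i,j] + e[i,j,t]`, where `m[i,j]` is the
  item's trait mean (defaults 0.55 positive / 0.15 negative items) plus a
  person factor shared within each valence block (SD 0.12). Defaults for
  the dispersion parameters were fixed once, prior to any acceptance
  measurement, to land within-person SDs near 0.13 and clear valence
  blocks in the correlation matrices.
- **Dynamics**: `e` is a stationary AR(1) (coefficient 0.3) whose
  innovations are correlated across items: +0.3 within a valence block,
  −0.2 between blocks, scaled to innovation SD 0.12. Initialization is
  from the stationary distribution, so there is no transient. Positive
  definiteness of the implied correlation matrix is checked at config
  construction and violations are rejected naming the parameters.
- **Censoring**: experience is `u = clamp(x, 0, 1)`. Clamping (rather
  than a logistic squash) is deliberate: it produces the exact-zero point
  mass that the zero-inflated beta models target, concentrated on
  low-mean negative items.
- **Read-out**: the VAS arm records `round(100·u)` (an integer, as a
  slider reports); the Likert arm records the 7-category thresholding of
  that same granularity of experience (`threshold_only`), optionally
  preceded by a zero-attraction step (`u < 0.10 → 0`) for experiments
  about stronger floor effects. Under `threshold_only` the Likert arm is
  *exactly* the process the thresholding counterfactual hypothesizes —
  the ground-truth condition in which explained fractions should approach
  1.
- **Missingness** is MCAR at the whole-beep level with person-specific
  rates drawn from a Beta with mean 0.33; the concentration (default 10)
  is a package choice, as no mechanism or spread is given anywhere for
  it. Durations are lognormal(log 135, 0.3) per survey. Criterion scores
  (BSI and three DASS subscales) load (default 0.5) on the standardized
  difference of the negative- and positive-block person factors plus unit
  normal noise — the simplest structure that yields positive correlations
  for negative items and negative ones for positive items.
- **Group sizes** default to 63 Likert / 56 VAS.

What the generator deliberately does **not** emulate: measurement
reactivity, time-of-day effects, MNAR missingness, response styles beyond
thresholding, or any arm difference in criterion-score informativeness.
The last point matters for interpretation: in this generator both arms
carry the same latent signal about the criteria, and thresholding barely
attenuates person-level means, so the generator does *not* reproduce a
large criterion-correlation gap between arms. Tests passing on this
generator therefore validate the machinery (estimators, models,
resampling, counterfactual logic) — they do not certify that real Likert
and VAS data differ only by thresholding; the thresholding counterfactual
exists precisely to measure how far that single mechanism goes.

## Within-person statistics

- Moments: mean; sample SD with divisor n−1; skewness as the moment
  estimator g1 = m3/m2^{3/2} with n-divisor central moments (undefined for
  constant series). Both estimator choices are documented here because
  several conventions exist; they are switchable in code.
- RMSSD and lag-1 autocorrelation run over the valid-pair set. Pairs may
  cross day boundaries by default (beep 6 → 7 of the next morning counts);
  an `exclude_overnight` flag provides the alternative, since overnight
  gaps are ~10 h rather than ~2 h.
- Correlation matrices are pairwise-complete Pearson over beeps where both
  items are observed (≥ 3 overlapping beeps, both with variation); group
  averages are plain per-cell means over participants with a defined cell
  (no Fisher-z, matching how such matrices are usually displayed;
  eigenvalues are computed on the group-mean matrix only when every cell
  is defined).
- Initial elevation is mean(day-1 beeps 1–6) − mean(beeps 7–84); the
  phenomenon is defined loosely in the literature, so the first-day window
  is this package's operationalization.
- Mode counting jitters the responses, fits a Gaussian KDE (Silverman
  bandwidth) on a 512-point unit grid, counts strict local maxima
  (boundary points included), and takes the majority vote over 10 jitter
  replicates (ties toward fewer modes). Two numerical guards matter:
  (1) **dequantization** — discrete responses are first spread uniformly
  over one category width (1/6 Likert, 1/100 VAS); without this the
  detector counts the Likert category grid itself, flagging the majority
  of Likert cells as multimodal, which is an artifact of the response
  format rather than of experience; (2) a **minimal relative height** of
  5% of the density peak, because isolated tail observations otherwise
  register as spurious modes (measured on calibration samples: the filter
  removes a ~10% spurious-mode rate on unimodal n = 80 draws without
  affecting well-separated bimodal ones). The Gaussian jitter SD (0.02)
  is small by design, increasing sensitivity to genuine multimodality.

## Group models

Every outcome's model is a *distributional* regression: the fixed effects
(scale with Likert baseline; valence effects-coded with negative = +1;
their interaction) act on all parameters — location, dispersion, and
boundary inflation where present. Family assignment per outcome: zero-
inflated beta for means, SDs and RMSSDs; beta without inflation for mean
absolute correlations; Gaussian with modeled log-SD for skewness, AR(1)
and initial elevation; zero-/one-inflated beta for missing proportions;
lognormal for survey-level durations (no valence term; participant random
intercept). The two inflation probabilities get independent logits — the
small corner where their sum could exceed 1 is guarded in the likelihood.

Backends:

- **mcmc** — adaptive Metropolis-within-Gibbs: elementwise random-walk
  updates with Robbins–Monro scale adaptation (target acceptance 0.44)
  for fixed effects and log-RE-SDs; vectorized elementwise updates for
  the crossed random intercepts (each participant's/item's acceptance
  depends only on its own rows); and *interweaving* moves that resample,
  from their exact Gaussian prior conditionals, the shared shifts between
  each cluster-constant coefficient and the mean of the corresponding
  random-intercept block (intercept ↔ participant and item intercepts,
  scale effect ↔ VAS participants' intercepts, valence effect ↔ item
  intercepts by block). Without interweaving those ridges mix an order
  of magnitude slower. Defaults: 3 chains, 1000 warmup, 1000 retained
  per chain with thinning 4 (chosen so bulk/tail ESS clears 500 at the
  default problem size); convergence is flagged, not silently ignored,
  when any rhat ≥ 1.02 or ESS ≤ 500. Priors: Normal(0, 2.5) on all link-
  scale coefficients, half-Normal(1) on random-effect SDs — weakly
  informative package choices, not a reproduction of any external prior
  specification.
- **map_laplace** — fixed-effects ML with a weak Normal(0, 5) ridge for
  numerical stability (its influence on estimates is below 1e-3 on the
  link scale at the default sizes), analytic gradients, and a Gaussian
  approximation from the finite-difference Hessian of the gradient.
- **cluster_bootstrap** — the same penalized ML refit on B resamples of
  participants with replacement within arm (warm-started at the full-data
  solution), yielding draw-like replicates. Random effects are omitted in
  the two ML backends; the bootstrap recovers cluster-level uncertainty
  by design, which is why it (not the Laplace) is the recommended fast
  backend for interval statements.

EMMs condition random effects at zero and average the response-scale
expectation over the two valence levels (not the linear predictor at
valence 0 — for nonlinear links these differ). Zoib expectation:
`(1−π0−π1)·μ + π1`; variance `μ(1−μ)/(1+φ)` (interior component);
lognormal location is reported as the median `exp(μ)`. "HDI" on bootstrap
replicates is a deliberate, documented abuse of terminology — the interval
is computed identically to the posterior case.

The HDI itself is the shortest contiguous window of sorted draws, with the
endpoints of all windows within 0.5% of the minimal width averaged: the
width profile of a symmetric density has a flat valley and the plain
arg-min endpoint is noticeably noisy (~n^{-1/3}); the averaging roughly
halves that noise and is inert for clearly skewed densities.

Criterion correlations z-score the per-person item means and the criterion
within each arm, so each item's regression slope *is* the Pearson r; the
arm-level summary is the average |r| over the 14 items, bootstrapped at
the participant level, with the VAS − Likert difference summarized per
replicate.

## Resampling

The permutation test moves whole participants between arm labels (the
within-person dependence travels with the matrix), recomputes the per-pair
difference in group-mean correlations, and uses the add-one two-sided
p-value `(1 + #{|perm| ≥ |obs|})/(N_P + 1)` — never exactly zero, and
exact type-I validity at any N_P (default 500, α = 0.10). Pairs undefined
for every member of one arm are skipped and reported; defined subsets use
pairwise participant deletion.

## Thresholding counterfactual

Cut points default to k/7 (equal-width bins; configurable), category
values to (k−1)/6, the top bin closed at 1. "Explained fraction" is
`(Δ_orig − Δ_thr)/Δ_orig`, which is 1 when thresholding reproduces the
whole gap and 0 when it changes nothing; values outside [0, 1] are
legitimate and occur. Uncertainty comes from a participant cluster
bootstrap of the entire pipeline (statistic recomputation included).
Because the estimator is a ratio, it is reported as *unstable* —
a diagnostic, not a number — when |Δ_orig| falls below a guard (default
1e-3) in more than 10% of replicates.

A quantified caveat from validation runs: with ~60 independent
participants per arm and the default person-level SD (0.12), the
between-arm sampling SD of the within-person-mean gap (~0.016) is of the
same order as the gap the thresholding mechanism itself produces (~0.02).
The explained fraction for means is therefore seed-sensitive at this
design size even when thresholding is the *true* mechanism: its bootstrap
HDI covers 1 at roughly its nominal rate, but its point value can sit far
from 1 on individual draws. Statistics whose gaps are larger relative to
between-person noise (skewness, AR(1), mean absolute correlation) are far
more stable. This is a property of the design size, not of the estimator
— the same instability would affect any analysis of a single study that
small.

## Problem sizes in the test suite

The suite validates at deliberately chosen sizes: oracle equivalence on
1,000 random series (tolerance 1e-12 against independent loop-based
implementations); permutation calibration on 200 null studies of 30+30
participants at T = 40 with 500 permutations; zoib parameter recovery on
50 studies of 60+60 with bootstrap B = 200; AR(1) consistency at
T = 5,000; mode-detector accuracy on 100 + 100 calibration samples of
n = 80; HDI checks at 100,000 draws. These sizes give the statistical
assertions comfortable margins while keeping the full suite in the
minutes range.

## Known limitations

- The MCMC backend is a general-purpose sampler, not Hamiltonian; very
  weakly identified parameters (e.g. inflation effects in cells with few
  boundary values) mix slowly and are the usual cause of a non-converged
  flag.
- Random effects are intercepts-only by default; the fuller structure
  (scale slope by item, valence slope by participant) is configurable but
  slows mixing and is not exercised by the default pipeline.
- EMMs condition on random effects at zero rather than marginalizing over
  them; for the logit link the two differ by the usual attenuation factor.
- The post-EMA experience questionnaire (cumulative ordinal outcomes) is
  out of scope; so are estimated or person-specific thresholds and
  response-process models richer than thresholding.
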
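# emascale

Tools for comparing **Likert** and **visual-analogue (VAS)** response scales
in ecological momentary assessment (EMA) studies.

In EMA, participants rate momentary affect ("Happy", "Sad", "Anxious", ...)
several times a day on their phones. Whether an item is answered on a
7-point Likert scale or a continuous 0–100 slider is a design choice with
real statistical consequences: bounded scales censor low-intensity
experience into exact zeros, coarse scales quantize small fluctuations, and
both effects propagate into within-person means, skewness, temporal
dynamics, and correlations with clinical baseline questionnaires. This
package provides, for researchers designing or analyzing two-arm EMA
studies:

- a **synthetic study generator** — a censored, cross-sectionally
  correlated AR(1) latent-affect process read out either at VAS granularity
  or through a 7-category threshold process, with realistic missingness,
  survey durations, and psychopathology criterion scores;
- the **within-person statistic battery** — means, SDs, skewness (g1),
  RMSSD and lag-1 autocorrelation over valid consecutive-beep pairs,
  KDE-based mode counts, pairwise-complete item correlation matrices,
  initial elevation, missingness proportions;
- **group inference** with bounded-response distributional models —
  zero-/one-inflated beta, Gaussian, and lognormal regressions in which
  response scale, item valence (effects coded), and their interaction act
  on *every* distributional parameter, with crossed random intercepts,
  reported as estimated marginal means (EMMs) with 90% highest-density
  intervals;
- a **permutation test** for differences in the 91 within-person item-pair
  correlations (whole participants shuffled between arms);
- the **thresholding counterfactual** — discretize the VAS arm through
  equal-width bins and measure what fraction of each observed scale
  difference pure discretization explains.

## The models in brief

Responses are first normalized to the unit interval: Likert `(k−1)/6`,
VAS `v/100`. For a statistic y bounded in [0, 1] (e.g. within-person
means) the group model is a zero-inflated beta distributional regression

    y = 0                with probability π0
    y ~ Beta(μφ, (1−μ)φ) otherwise,

    logit(μ)  = β0 + β1·scale + β2·valence + β3·scale×valence + u_person + u_item
    log(φ)    = γ0 + γ1·scale + γ2·valence + γ3·scale×valence
    logit(π0) = δ0 + δ1·scale + δ2·valence + δ3·scale×valence

with Likert as the baseline scale and valence effects-coded (negative = +1).
Skewness, AR(1) and initial elevation use a Gaussian family with modeled
log-variance; missingness adds one-inflation; durations are lognormal.
Three interchangeable backends fit the same model: an adaptive
Metropolis-within-Gibbs sampler (with interweaving moves for the
fixed-effect/random-intercept ridges and arviz rhat/ESS diagnostics), a
penalized-ML Laplace approximation, and a participant cluster bootstrap.

The thresholding counterfactual asks: if Likert respondents actually
experience affect at VAS granularity but must press one of seven
categories, how much of each observed arm difference does that mapping
produce? With cut points k/7 and Δ = S(VAS) − S(Likert),

    explained(S) = (Δ_orig − Δ_thresholded-VAS) / Δ_orig,

bootstrapped over participants, overall and by valence stratum.

## Worked example

The numbered scripts under `analysis/` run the full study analysis on a
synthetic two-arm study (63 Likert / 56 VAS participants, 14 items, up to
84 beeps) and write their tables under `results/`:

```
$ python analysis/01_simulate_study.py
generated 94122 records for 119 participants (63 Likert / 56 VAS)
observed beeps per participant: mean 56.5 of 84
fraction of exact-zero responses: Likert 0.312, VAS 0.150

$ python analysis/02_descriptives.py
118 participants pass inclusion; 108 eligible for lagged statistics
...
bimodal cells: Likert 0.029, VAS 0.094
cross-arm correlation of the 91 mean pairwise correlations: 0.993

$ python analysis/05_permutation_test.py
39 of 91 pair correlations differ at alpha = 0.1
of the significant pairs, 100% have the larger |r| in the VAS arm

$ python analysis/06_thresholding_counterfactual.py
wp_mean        original gap -0.0040  explained -102% (90% HDI [-1264%, +982%])
wp_skew        original gap -0.2091  explained +146% (90% HDI [+28%, +656%])
ar1            original gap +0.0434  explained +118% (90% HDI [+75%, +178%])
mean_abs_corr  original gap +0.0304  explained +111% (90% HDI [+69%, +169%])
```

Reading this: the Likert arm of this study is *generated* by thresholding
VAS-granularity experience, so every genuine arm difference is
discretization by construction. The counterfactual correctly attributes
the autocorrelation and correlation gaps to thresholding (explained ≈ 100%,
HDIs covering 1). For within-person means the between-arm sampling noise
at ~60 participants per arm (SE ≈ 0.016) is as large as the mechanism's
expected gap (≈ +0.02), so this particular draw shows a near-zero original
gap and the explained fraction is unstable — the wide HDI says exactly
that. Exact zeros (0.31 vs 0.15) and skewness are markedly higher in the
Likert arm, and item correlations are uniformly attenuated, mirroring the
qualitative pattern such threshold processes produce in real scale
comparisons.

A `emascale` command-line wrapper exposes each stage
(`simulate`, `describe`, `infer`, `permtest`, `threshold`, `run`).

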
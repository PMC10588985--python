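# Methods

## The model

`phasecoh` models trial-level phase angles from frequency-tagged EEG/MEG
experiments. At one analysis frequency, the phase of trial *k* for
participant *p*, condition *c*, electrode *e* is wrapped-Cauchy distributed,

```
theta_pcek ~ WrappedCauchy(mu_pce, gamma_pce)
p(theta)   = (1 / 2pi) sinh(gamma) / (cosh(gamma) - cos(theta - mu))
```

The wrapped Cauchy is used because, unlike the wrapped Gaussian, it has a
closed-form density, and its mean resultant is simply `R = exp(i mu - gamma)`.
The circular variance is therefore `S = 1 - exp(-gamma)`, which connects the
model scale directly to the inter-trial phase coherence (ITPC), the quantity
practitioners already report.

**Dispersion regression.** The scale is driven by a linear model on the logit
of the circular variance:

```
S_pce     = logistic(upsilon_pce)
gamma_pce = -log(1 - S_pce)            # jointly: gamma = softplus(upsilon)
upsilon_pce = alpha_c + beta_pc + delta_ce
```

- `alpha_c` — condition effect. The scientific output is the condition-level
  mean resultant `R_c = 1 - logistic(alpha_c)` and its contrasts
  `Delta R = R_c1 - R_c2`.
- `beta_pc` — participant-by-condition slopes, multivariate Student-t across
  conditions (heavy tails absorb unusually strong or inattentive
  participants; the across-condition correlation pools information about a
  participant's overall attentiveness).
- `delta_ce` — electrode slopes, Gaussian, pooled within condition only.

**Mean-phase prior.** Each cell's location `mu_pce` is the angle of a planar
pair `(x, y)` with a rotation-invariant "Bundt" prior: the log-prior adds the
Gamma(shape, rate) log-density of the radius `rho = sqrt(x^2 + y^2)`. This
gives `mu` a uniform prior on the circle while letting a gradient-based
sampler cross the `+pi/-pi` boundary freely — a plain `Uniform(-pi, pi)`
prior has the wrong topology for MCMC. With the default `shape = rate = 100`
the radius concentrates at 1 with sd 0.1; the radial profile is
inconsequential (only the angle enters the likelihood), it merely keeps
sampling away from the origin where the angle is undefined.

Because the log-prior adds the Gamma density of `rho` *without* the polar
area Jacobian, the radial marginal it actually implies is
`rho ~ Gamma(shape + 1, rate)` (mean 1.01 at the defaults). Prior draws in
`draw_params_from_prior` sample exactly that density so that prior draws and
the sampled posterior target the identical joint distribution — the property
simulation-based calibration (SBC) relies on. The angle is uniform either
way.

## Priors and hyperparameters

| parameter | prior | default | why |
|---|---|---|---|
| `S_c = logistic(alpha_c)` | Beta(a, b) | a=5, b=2 | frequency-tagged effects are weak: circular variance likely above 1/2 (prior mean 0.71) |
| `beta_p.` | multivariate-t(nu, 0, diag(sb) R diag(sb)) | — | robustness to outlier participants |
| `nu` | fixed, or Gamma(2, 0.1) on nu-2 | 30 | fixing nu avoids divergences at small participant counts |
| `sigma_beta[c]`, `sigma_delta[c]` | half-normal(scale) | scale 1 | weakly informative on the logit scale |
| `R` (slope correlation) | LKJ(eta) | eta 2 | mildly favours independence |
| `delta_ce` | Normal(0, sigma_delta[c]) | — | electrode pooling within condition |
| `(x, y)_pce` | Bundt(shape, rate) | 100, 100 | uniform circular location |

All are exposed in `PriorConfig` and serialisable to YAML
(`phasecoh config init`).

`alpha_c` is identified only through the shrinkage of `beta` and `delta`
toward zero — the slopes are not sum-constrained. Consequently `R_c` is
interpretable as the condition-level coherence of a typical participant and
electrode, and point estimation at very small layouts (a handful of
participants *and* electrodes) lets the slopes absorb part of the condition
effect, pulling the mode toward the Beta prior. At study-scale layouts
(16 participants, 32 electrodes) the mode recovers a known `R_c = 0.5` to
within 0.03. Full posterior inference is well calibrated at all tested
sizes (see SBC below).

## Posterior computation

The sampler is an in-package implementation of multinomial NUTS
(no-U-turn Hamiltonian Monte Carlo) with dual-averaging step-size adaptation
(target acceptance 0.9 by default) and diagonal mass-matrix estimation in an
adaptation window covering the middle of warmup. The first half of each
chain is warmup and discarded; energies and divergences (energy error
> 1000) are recorded per iteration. Gradients of the joint log-density are
analytic and verified against central finite differences in the test-suite;
a numba-compiled kernel and a vectorised numpy reference implementation are
cross-checked against each other to 1e-10.

The sampling space is unconstrained and non-centred:

- `beta = diag(sigma_beta) L z / sqrt(u)` with `z ~ N(0, I)` and
  `u ~ Gamma(nu/2, nu/2)` — the scale-mixture form of the multivariate t —
  to avoid funnel geometry;
- `delta = sigma_delta * z`;
- scales on the log scale; the slope correlation through canonical partial
  correlations `z_ij = tanh(y_ij)`, whose independent scaled-Beta
  factorisation with shape `eta + (C - 2 - j)/2` is exactly the LKJ(eta)
  distribution;
- reported draws are always the centred quantities.

Numerical guards reject (as divergent, never as exceptions) states where
`gamma` underflows below 1e-12, a planar pair reaches the origin, or a
scale-mixture weight under/overflows.

`map_estimate` maximises the same unconstrained density with L-BFGS-B and
the analytic gradient (optionally multi-start). The mode is taken in the
non-centred space because the centred mode is improper (the
`sigma -> 0` funnel spike).

Diagnostics — split R-hat, bulk/mean ESS and E-BFMI — are computed with
arviz behind thin validating wrappers. E-BFMI uses the standard definition
`mean(diff(E)^2) / var(E)`; for i.i.d. energies this is 2, and values below
~0.3 indicate poor energy exploration. HDIs are the narrowest contiguous
window of sorted draws, leftmost on ties (HDIs of multimodal draws are
non-unique, so the tie-break is part of the contract); contiguity matches
the interval plots the model's summaries feed.

## Frequentist baseline

- Per-cell ITPC tables with explicit missing-cell masking, and
  participant-averaged electrode difference maps (optionally mean-centred
  across electrodes, since the ITPC's upward bias shifts all electrodes
  together).
- Paired Wilcoxon signed-rank tests: exact enumeration p-values for
  n <= 25 without ties, normal approximation with continuity correction
  otherwise; zero differences dropped and counted. The Hodges-Lehmann
  location estimate and confidence interval come from the Walsh averages
  with critical values from the exact null distribution of W+ (computed by
  polynomial convolution; normal approximation beyond n = 150).
- Cluster-based permutation testing in the Maris-Oostenveld style: paired
  t statistics per electrode (signed-rank z optional), two-sided forming
  threshold p < 0.05, sign-homogeneous connected supra-threshold clusters
  under a user-supplied adjacency (a k-nearest-neighbour builder from 2-D
  montage coordinates is provided, default k = 4), cluster mass = summed
  statistic, max-|mass| permutation null from within-participant condition
  swaps, `p = (1 + #{null >= obs}) / (1 + n_perm)`. All four choices are
  arguments.

## Validation experiments and what they show

The generator used throughout is the model itself, at the published study
designs: the bias/detection study uses 5 participants, 2 conditions,
8 electrodes, 10 trials with ground-truth coherences drawn uniformly on
(0, 1) (the Beta baseline prior replaced by a uniform); the `phrase` preset
is 16 x 6 x 32 x 24 and the statistical-learning preset 39 x 2 x 64 x 132
(three blocks of 44 trials). Participant and electrode spreads come from
their hyperpriors, so simulated datasets carry realistic between-participant
and between-electrode heterogeneity. What the generator does **not**
emulate: spatially correlated electrode responses, non-stationarity across
blocks, artifacts, or any deviation of real phase distributions from the
wrapped-Cauchy family — so passing tests demonstrate internal consistency
and calibration under the model's own assumptions, not robustness to
misspecification.

- **Bias study** (ratio of estimated to true `Delta R`): the ITPC arm
  averages per-cell ITPC over electrodes then participants; its per-cell
  positive bias is larger for the less coherent condition, so the
  difference ratio is systematically attenuated below 1, markedly so for
  small true differences. The Bayesian posterior-median ratio centres on 1.
  Because the true difference is drawn uniformly, it can fall below the
  design's sampling-noise floor, where the ratio's tails are Cauchy-like
  and its mean does not exist; ratio *summaries* therefore condition on a
  resolvable true difference (|Delta R| >= 0.1) while every per-dataset
  record is still emitted.
  Detection: zero outside the 95% HDI (Bayes) versus a two-sided paired
  Wilcoxon at 0.05 on electrode-averaged ITPC (which, at 5 participants,
  cannot reach p < 0.05 at all — the exact attainable level is 0.0625).
- **SBC**: ranks of prior-drawn truths among 50 thinned posterior draws,
  200 simulations at a reduced 4 x 2 x 4 x 8 layout with short
  tree-depth-capped fits (2 chains x 500 iterations, depth cap 5). Ranks
  are recorded for `Delta R` and for `R_1`. A chi-square uniformity test
  and a Monte-Carlo simultaneous 99% ECDF band both pass; this is also the
  end-to-end evidence that the short capped fits mix adequately. The
  negative control doubles `gamma` inside the fitted likelihood: the
  corruption distorts both conditions alike (fitted `R' = sqrt(R)`), which
  largely cancels in `Delta R` but grossly skews the `R_1` ranks — the
  control is therefore asserted on `R_1`.
- **Data-efficiency curves** re-run the Wilcoxon interval and the posterior
  HDI while participants are removed from the end of the recording order,
  or trials are truncated per cell, emitting one tidy row per subset size.
  `nu` stays fixed at 30 in these fits.

## Problem sizes and runtime choices

Test-suite and acceptance-script experiment sizes are desk-scale: 20 (tests)
or 10 (script) recovery replicates at 8 x 2 x 8 x 20; 30-40 bias-study
datasets; 120-200 SBC simulations; 500-1000 cluster null replicates with
500 permutations each. Calibration fits use 2 chains of 500-800 iterations
with tree depth capped at 5-6 and target acceptance 0.8-0.85 — a capped
NUTS remains exactly invariant for the posterior, and the SBC results
document that these settings are sufficient. Interactive analyses should
use the defaults of `sample_posterior` (4 chains x 4000 iterations, target
acceptance 0.9, depth cap 10).

## Known limitations

- Single-frequency fits only; responses at harmonics are fitted
  independently. No block effects and no spatially correlated electrode
  priors.
- The wrapped-Cauchy family is unimodal; bimodal phase distributions
  (e.g. mixed response polarities) are outside the model.
- Condition-level `R_c` point estimates at very small layouts inherit the
  identifiability caveat above; report contrasts (`Delta R`) or full
  posteriors instead.
- The cluster permutation test licenses cluster-level claims only;
  electrode-level claims come from the Bayesian electrode contrasts.
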
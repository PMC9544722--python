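# Methods

`pedfit` estimates the additive genetic variance (V_A), heritability (h²)
and evolvability (I_A) of non-Gaussian fitness components in a pedigreed,
open wild population, and quantifies — by simulation — the power of a given
pedigree design to detect small V_A. This note documents the models, the
numerical choices, and what the synthetic data do and do not emulate.

## The animal models

All analyses are univariate animal models: generalised linear mixed models
in which each individual carries an additive genetic value `a_i`, with
`a ~ N(0, V_A A)` and `A` the numerator relationship matrix derived from
the pedigree.

* **Lifetime fitness** (number of local fledglings produced over life) is
  zero-inflated Poisson. An individual is a *structural zero* with
  probability `logit⁻¹(η_zi)` — biologically, it never enters the local
  breeding population — and otherwise produces `Poisson(exp(η_pois))`
  fledglings. Each latent predictor has its own intercept, a dead/alive
  status fixed effect (alive birds are censored by the end of a study),
  additive genetic and hatch-cohort random intercepts, and a residual: the
  logit residual variance is fixed to 1 (it is not separately identifiable),
  the log-scale residual is estimated (lifetime fitness is overdispersed).
  No covariance between the two components is modelled.
* **Annual reproductive success** (ARS; fledglings per year, at most one
  brood of up to three chicks) is Poisson/log with intercept, a linear age
  effect, and additive genetic, permanent-environment and year random
  intercepts.
* **Adult annual survival** (AAS) is binary/logit with the same structure
  and the residual variance fixed to 1.

### MCMC scheme

Each observation carries a latent value η (linear predictor plus residual);
conditional on η the model is linear-Gaussian. The sampler combines:

* **Pólya-Gamma augmentation** for logit likelihoods: with
  `w ~ PG(1, η)` the Bernoulli likelihood is Gaussian in η, so logit
  latents are Gibbs-updated exactly (Devroye's alternating-series sampler),
  and the latent can then be integrated out analytically, leaving
  pseudo-observations `(y − ½)/w` with variance `v_e + 1/w` for the
  location/variance updates.
* **Element-wise adaptive random-walk Metropolis** for log-link (count)
  latents, several sweeps per iteration, with step sizes tuned to ~44%
  acceptance during burn-in only.
* **Joint breeding-value draws.** All `a_i` are sampled in one block by
  perturb-and-solve: a prior draw (gene dropping) plus a solve of the
  mixed-model precision `A⁻¹/s² + diag(d)` with a fixed-pattern sparse
  Cholesky (symbolic analysis once per pedigree under a reverse
  Cuthill–McKee ordering; numeric refactorisation each iteration).
  Single-site updates were abandoned: at study scale they yielded effective
  sample sizes of ~10 per 1000 retained draws.
* **Marginal scale moves.** The variance scale of every random term also
  gets a random-walk Metropolis update with the whole effect vector
  integrated out of the likelihood (one extra sparse factorisation per
  proposal), which removes the funnel-shaped coupling between a variance
  and its effects.
* **Zero-inflation augmentation, collapsed.** The structural-zero indicator
  of each observed zero is resampled with the count latent integrated out by
  Gauss–Hermite quadrature; latents of non-structural zeros are then
  re-imputed by exact rejection sampling (acceptance `exp(−λ)`), with a
  Laplace fallback for pathologically unlikely rows. Keeping prior-imputed
  latents inside the Poisson-side updates instead was a measured mistake —
  83% of rows carried no information and the residual variance chain became
  an AR process with autocorrelation ≈ the inactive fraction.
* **A ridge move for logit components.** Near-saturated binary traits leave
  the *latent* scale only weakly identified (the likelihood is almost
  invariant to rescaling the linear predictor once most probabilities are
  near 0 or 1; only the unit residual anchors it). A Metropolis move
  proposing `(β, u, s²) → (cβ, cu, c²s²)` with the exact prior/Jacobian
  correction traverses that ridge.

### Priors

Variance components default to parameter-expanded half-t priors with 1
degree of freedom (half-Cauchy) on the standard deviation, scale 1 — the
effect enters the predictor as `ξ·u` with `u ~ N(0, s²·structure)`,
`ξ ~ N(0, scale²)`, `s² ~ InvGamma(ν/2, ν/2)`. Two alternatives are
config options: plain inverse-gamma (no expansion; used by the
simulation-based calibration test because it is easy to sample), and
**half-normal** via parameter expansion with the mixing scale fixed
(`s² ≡ 1`), a non-centred parameterisation. The power study uses the
half-normal with scale 5 on the genetic term of its model fits (other
terms keep the default): the data-scale variance
targets imply latent variances of ~5–17 on the logit scale, squarely in the
weak-identifiability regime, and the half-normal both regularises the
latent ridge and removes the small-variance funnel. Location effects get
independent N(0, 100) priors (logit/log scales rarely exceed ±10; fully
diffuse priors let quasi-separated contrasts wander destructively). An
estimated residual has an inverse-gamma prior with ν = 0.002, scale 1.

### Inference summaries and diagnostics

Point estimates are posterior modes from a Gaussian-kernel density estimate
with Silverman's bandwidth on the retained draws (documented because modes
of near-boundary variance posteriors are bandwidth-sensitive); intervals
are 95% highest-posterior-density (narrowest) intervals, matching the
zero-leaning lower bounds typical of variance components. Diagnostics per
parameter: autocorrelation-based effective sample size (via arviz), lag-1
autocorrelation of retained draws, and the Heidelberger–Welch stationarity
test (Cramér–von Mises statistic of the cumulative-sum bridge, spectral
density at zero estimated from the final half of the chain, 5% level).
Chains below the target ESS trigger a warning, never silent acceptance.

## Scale transformation

Latent-scale posteriors are converted draw-by-draw to the data scale
(population mean, V_P, V_A, h², I_A), then summarised — ratios are formed
per draw, never from summarised numerators and denominators.

* log link: `mean = exp(μ + s²/2)`, `V_P = mean + mean²(e^{s²} − 1)`,
  `V_A,obs = mean²·V_A` (so the per-draw evolvability equals the latent
  variance).
* logit link: `mean = E[logit⁻¹(x)]` and `Ψ = E[dp/dx]` for
  `x ~ N(μ, s²)` by Gauss–Hermite quadrature (32 nodes; 64 above s² = 2; a
  dense trapezoid rule over the standard normal above s² = 4, where
  Hermite rules would need impractically many nodes), with
  `V_P = mean(1 − mean)` and `V_A,obs = Ψ²·V_A`. Node-doubling stability
  to 1e-8 is enforced.

The total latent variance s² includes every variance component *and* any
residual the model fixes (the unit logit residual), and the transform is
evaluated at the reference level of the fixed effects (dead individuals;
the age covariate at its reference age of 1), so h² is conditional on the
variance explained by fixed effects. The evaluation point is a genuinely
open choice; the reference-level convention is the package's.

## Synthetic data

The generator emulates an open colonially breeding seabird population:

* **Pedigree.** Discrete generations of `years_per_generation` breeding
  seasons. Unmarked immigrants join every generation's pool and never enter
  the pedigree (their offspring carry a missing parent link); local
  fledglings recruit with a fixed probability into the next generation.
  Breeders are seasonally monogamous with between-year mate fidelity, and
  pairs fledge `min(Poisson(rate), 3)` chicks per season with a persistent
  lognormal pair-quality effect — the combination of multi-year careers and
  quality heterogeneity is what produces realistically large full- and
  half-sibship counts. Defaults are calibrated to the emulated study's
  printed structure: ~6,300 records, maximum depth 5 generations, ~2,400
  paternities/maternities. The calibrated configuration gives a marked
  share of breeding activity of ~0.4 (the census immigrant share is
  higher; immigrant-heavy colonies are compatible with a larger marked
  share of *fledgling production* because established local recruits
  out-produce the average breeding attempt). Full- and half-sib pair
  counts land ~30–40% below the emulated study's — real sibship-size
  overdispersion is stronger than the lognormal quality model — so
  synthetic pedigrees are somewhat less informative about V_A than the real
  one; power estimates on them are conservative.
* **Lifetime fitness.** Structural-zero and count latents as in the
  analysis model, including a unit-variance logit residual so generator and
  model live on the same latent scale. Defaults are calibrated (by
  quadrature, jointly for the intercepts) to the raw marginal moments of
  the emulated data: 87.2% zeros and mean 0.72 fledglings, i.e. a
  structural-zero probability of 0.868 and a conditional Poisson mean of
  5.47, with hatch-cohort variance 0.05 and log-scale overdispersion 0.2
  (values in the range implied by the study's data-scale phenotypic
  variances; not separately printed). Censoring status is drawn from an
  independent lifespan process (geometric adult lifespan, mean 6.5 years).
* **Annual components.** Per-year rows from recruitment (age 1) until
  death; ARS is truncated Poisson (max 3), survival is Bernoulli-logit with
  a unit residual and decides continuation; age enters both latents
  linearly. Intercepts are calibrated by simulation so the realised tables
  have mean ARS ≈ 0.70 and mean AAS ≈ 0.85 given the default variance
  structure and age slopes (+0.05/yr ARS, −0.10/yr AAS, latent scale).
* **Gene dropping.** Founders draw `N(0, V_A)`; descendants get the
  mid-parent value plus a Mendelian deviation with variance
  `V_A(0.5 − 0.25(F_s + F_d))` (unknown parents contribute zero-mean
  founder draws), so simulated values have covariance exactly `V_A·A`.

What passing tests on synthetic data do *not* show: robustness to pedigree
errors (misassigned social parentage), non-random immigrant settlement,
density dependence, sex differences, or environment–genotype correlation —
none of which the generator produces.

## Power study

For each target variance and replicate: gene-drop breeding values, simulate
lifetime fitness (with completed life histories — the power replicate asks
about the component itself, not end-of-study censoring), refit the
zero-inflated Poisson animal model, transform, and summarise. A replicate
*detects* the variance when the lower 95% HPD bound exceeds 0.0001.
Replicates whose target-variance chain falls below an ESS floor are
flagged, excluded from aggregates and reported.

Targets are specified on the **data scale** — V_A for the zero-inflation
component, I_A for the Poisson component — and mapped to latent variances
by inverting the link transform: `v_a = log(1 + I_A)` (log link; the exact
lognormal convention) and a fixed-point solve of `v_a = V_A,obs/Ψ(v_a)²`
(logit link), holding the calibrated intercept fixed (holding the marginal
*mean* fixed instead is infeasible: at a structural-zero probability of
0.868 the data-scale additive variance is bounded above by ≈ 0.046).
Recovery is assessed on the same scale. Latent-scale injection is
available as a config option, but on the latent scale the posterior of a
small V_A on a binary trait is an order of magnitude wider than any
interval detectable by the HPD-threshold rule, at any realistic pedigree
size — the detection behaviour this module reproduces exists only on the
data scale.

The extended-design scenario continues the breeding dynamics (same
immigrant influx and recruitment) for extra generations before simulating,
so record counts roughly double over four added generations.

## Problem sizes

Shipped defaults fit the full ~6,300-record pedigree. The test suite and
the acceptance script run the recovery studies on structurally identical
pedigrees scaled to ~1,300 and ~2,500 records with 5–10 replicates per
target and chains of 6,000–8,000 iterations — sizes chosen so a complete
desk run stays in the tens of minutes; the replicate scatter of posterior
modes at those sizes is the dominant uncertainty and the test bands are
three-sigma Monte Carlo envelopes for it.

## Known limitations

* Latent-scale variance components of near-saturated logit components are
  reported as sampled but are only weakly identified; data-scale summaries
  are the meaningful ones there.
* The Heidelberger–Welch test is a 5% level test: ~5% of healthy chains
  fail it by construction.
* No multi-trait models, no covariance between the zero-inflation and
  count components (modelling it did not improve fit in the emulated
  study), no genomic relatedness, no DIC-based model comparison.
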
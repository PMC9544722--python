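# pedfit

Quantitative genetics of fitness in pedigreed wild populations.

Additive genetic variance in fitness is the quantity that sets a
population's rate of adaptation, yet in wild populations it is notoriously
hard to estimate: fitness data are zero-inflated counts, pedigrees are
shallow and porous (immigrants breed but are never pedigreed), and the
truly interesting values are small. `pedfit` implements the full analysis
chain for this problem, motivated by long-term individual-based studies of
colonially breeding seabirds:

* **Pedigree handling** — reading/validation, pruning to phenotyped
  individuals and their ancestors, structure summaries (paternities,
  sib-pair counts, depth), inbreeding coefficients, and the sparse inverse
  of the additive relationship matrix `A` by Henderson's rules.
* **Bayesian animal models by MCMC** — zero-inflated Poisson (lifetime
  fitness), Poisson/log (annual reproductive success) and binary/logit
  (annual survival) mixed models with pedigree-structured additive genetic
  effects, parameter-expanded variance priors, Pólya-Gamma augmentation and
  joint sparse-Cholesky updates. Posterior modes (kernel density), 95% HPD
  intervals, effective sample sizes and Heidelberger–Welch diagnostics.
* **Data-scale conversion** — latent-scale posteriors converted per draw to
  the observed scale: population mean, phenotypic variance V_P, additive
  genetic variance V_A, heritability h² = V_A/V_P and evolvability
  I_A = V_A/mean².
* **Synthetic data** — a colony simulator (immigrant influx, mate fidelity,
  recruitment; calibrated to a ~6,300-record, 5-generation pedigree),
  gene-dropped breeding values, and zero-inflated lifetime / annual fitness
  generators calibrated to realistic raw moments (~87% zero lifetime
  fitness, mean 0.72 fledglings; annual reproduction 0.70, survival 0.85).
* **Power analysis** — replicate simulate-and-refit studies asking how
  small a V_A a given pedigree design can detect (lower 95% HPD bound
  above 0.0001), including extending the pedigree by future generations.

## Worked example

```python
import pedfit as pf
from pedfit import model as M
from pedfit import scale as S

# a synthetic colony pedigree with the default (study-scale) structure
ped = pf.simulate_pedigree(pf.study_default_pedigree_config(seed=1))
print(pf.summarize(ped))

# lifetime fitness for every individual, then the ZIP animal model
table = pf.simulate_lifetime(ped, pf.study_default_trait_params(va_zi=0.3), seed=2)
df = M.prepare_lifetime(table)
fitres = M.fit(df, ped, M.lifetime_model_spec(),
               M.McmcConfig(n_iter=8000, burn_in=3000, thin=5, seed=3))

# latent-scale posterior of the zero-inflation component's V_A ...
print(fitres.summarize("va_zi"))
# ... and the data-scale quantities, summarised per draw
draws, summaries = S.transform_posterior(fitres, component="zi")
print(S.summary_frame(summaries).round(4))
```

Output (abridged):

```
PedigreeSummary(n_records=6213, max_depth=5, n_paternities=2366,
                n_maternities=2257, n_fullsib_pairs=1237, ...)
PosteriorSummary(mode=0.9452, hpd_low=0.2670, hpd_high=2.1843, mean=1.1837)
           mode  hpd_low  hpd_high    mean
mean     0.8687   0.8507    0.8835  0.8671
v_p      0.1141   0.1029    0.1270  0.1152
v_a_obs  0.0084   0.0030    0.0155  0.0093
h2       0.0732   0.0249    0.1315  0.0803
ia       0.0110   0.0039    0.0209  0.0123
```

Read: the latent-scale posterior of the simulated additive variance (0.3
on the logit scale) is wide — its 95% interval (0.27, 2.18) brackets the
truth but barely excludes zero, the hallmark of binary-like traits whose
latent scale is only weakly identified.  On the data scale the same
posterior is far better behaved: an additive variance of ~0.008 in the
structural-zero probability (phenotypic variance 0.11), heritability ~7%
— the attenuation that makes fitness heritability so hard to measure.

A thin CLI mirrors the library (`pedfit simulate-pedigree`,
`simulate-phenotypes`, `summarize-pedigree`, `fit`, `transform`, `power`);
every run writes plain-text tables plus a JSON manifest with config,
seeds and input digests.

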
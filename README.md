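# dietmix

Bayesian estimation of predator diet proportions from fatty-acid (FA)
profiles, stable-isotope (SI) signatures, or both jointly.

Quantitative diet analysis from chemical markers faces two complementary
problems: SI data (typically δ¹³C and δ¹⁵N) are low-dimensional, so systems
with more than a few prey sources are under-determined; FA profiles are
high-dimensional but compositional (proportions of total lipid, summing to
one), so Gaussian mixing machinery does not apply directly. `dietmix`
implements a compositional mixing model for FA profiles in log-ratio space,
the standard linear mixing model for SI with additive trophic
fractionation, and their explicit combination in one posterior — for
ecologists estimating what fraction of a predator population's (or
individual's) assimilated diet each candidate prey source contributes.

## The model

Prey FA profiles are logistic-normal per species: with `alr` the additive
log-ratio transform, `alr(y_{i,s}) ~ N(μ_s, Σ_s)`. A predator consuming
diet proportions `π` has expected profile

    τ = C( Σ_s (π_s Φ_s) (κ_s ⊙ φ_s) )

where `C` is closure (normalization to unit sum), `Φ_s` the relative fat
content of prey species `s`, `κ_s` its per-FA conversion coefficients
(relative assimilation, identified only up to scale), and `φ_s` the
consumed prey profile. Observed predator signatures scatter around it:
`alr(t) ~ N(alr(τ), Σ_τ)`. SI signatures mix linearly with additive
fractionation: `t^SI = Σ_s π_s (x_s + γ_s)` plus residual noise, with
`γ_{s,iso} ~ N(ν, σ)` from feeding-trial priors. Diet proportions can be
modelled at the population level (Dirichlet prior), per individual
(hierarchical logistic-normal, internally in an orthonormal ilr basis), or
as a linear model on predator covariates. Conversion coefficients and fat
content carry moment-parametrized gamma/log-normal priors and can be
estimated from feeding trials with known diets.

Inference is by adaptive Metropolis-within-Gibbs MCMC with conjugate
updates where available; weakly identified predator residual covariances
are integrated out analytically. Three treatments of consumed prey are
available: `latent` (per-predator consumed prey items are sampled — the
full model), `linearized` (consumed-prey variability integrated by the
delta method; exact on the SI side), and `mean` (species means; fastest,
ignores that variability). See `docs/methods.md`.

## Worked example

Simulate the package's reference scenario (3 prey species, 30 samples
each, 12 FAs, 2 isotopes, 10 predators eating diet 0.2/0.3/0.5), then fit
the joint FA+SI population model:

```bash
dietmix simulate --seed 11 --out-dir demo
dietmix fit --config demo/run.yaml --markers both --prey-mode linearized \
    --chains 2 --iters 2000 --seed 3 --out-dir demo/fit \
    --truth demo/truth_pi.csv
```

The report (`demo/fit/report.md`) contains the posterior diet table:

```
| parameter   |   mean |   median |    sd |   ci90_lo |   ci90_hi |   rhat |     ess |
|:------------|-------:|---------:|------:|----------:|----------:|-------:|--------:|
| pi[sp1]     |  0.209 |    0.208 | 0.037 |     0.148 |     0.269 |  1.006 | 115.443 |
| pi[sp2]     |  0.330 |    0.328 | 0.041 |     0.268 |     0.406 |  1.018 |  94.753 |
| pi[sp3]     |  0.460 |    0.461 | 0.044 |     0.390 |     0.535 |  1.006 |  82.714 |
```

Read: the model attributes about 21%, 33% and 46% of the assimilated diet
to the three prey species (posterior means), with 90% credible intervals
of roughly ±0.07 around each — the simulated truth (0.20, 0.30, 0.50) is
inside every interval, as the report's recovery section confirms
(absolute errors 0.009–0.040, all intervals covering). Fractionation
coefficients land near their feeding-trial priors (≈1.0‰ and ≈3.4‰).
`rhat` near 1 and the effective sample sizes indicate the chains mixed;
`demo/fit/diagnostics.txt` lists the full convergence table.

Other entry points: `dietmix select-fa` ranks FAs by their contribution to
among-prey separation on constrained ordination axes and picks a subset
under a collinearity cap; `dietmix estimate-coeffs` estimates conversion
coefficients from a feeding trial with known diets; `dietmix scenario`
runs sensitivity grids (source separation, diet evenness, conversion
noise, collinearity). All of this is also available as a library
(`dietmix.mixing_model.build_model`, `dietmix.sampler.run_chains`, ...).

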
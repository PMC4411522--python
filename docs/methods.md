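# Methods

## Model

### Fatty-acid profiles

FA profiles are compositions: `p` proportions of total lipid summing to
one. All modelling happens in log-ratio coordinates. Prey individuals of
species `s` have `alr(y) ~ N(μ_s, Σ_s)`, with the additive log-ratio
transform taken against a reference FA (the last column by default; the
choice is a setting, recorded in outputs, and affects only the
coordinate system, not the model). Predator profiles are
closure-normalized mixtures of consumed prey profiles weighted by diet
proportions `π`, fat content `Φ` and conversion coefficients `κ`:

    τ_j = C( Σ_s (π_{j,s} Φ_s) (κ_s ⊙ φ_{j,s}) ),
    alr(t_j) ~ N(alr(τ_j), Σ_τ).

Because of the closure, `κ_s` and `Φ` are identified only up to
per-species multiplicative constants; `κ` draws are closure-normalized
when recorded, and `Φ` enters only through relative values.

### Stable isotopes

Prey SI signatures are multivariate normal per species. Predator
signatures are `t^SI_j = Σ_s π_{j,s}(x_{j,s} + γ_s) + ε`, with additive
per-species fractionation `γ_{s,iso} ~ N(ν_iso, σ_iso)` parametrized from
feeding-trial estimates. There is no default fractionation: SI models
refuse to run without a fractionation table, because silently assumed
trophic shifts are a classic source of silent bias. FA and SI tables may
cover different individuals — the model assumes only that prey samples
come from the same statistical populations and predator diets from the
same diet distribution.

### Consumed-prey treatment

Predators do not eat species-mean prey; they eat individual prey items.
Three treatments are implemented:

* `latent` (default): per-predator, per-species consumed profiles
  `φ_{j,s}` (and consumed SI values) are sampled as latent variables from
  the species distributions. This is the full model; with many FAs it
  carries hundreds of latent dimensions and mixes slowly (see Sampling).
* `linearized`: the consumed-prey variability is integrated out
  analytically — exactly on the SI side (the mixture is linear in the
  consumed values, giving `Var = Σ_s π_s² Σ_s^SI + residual`), and by the
  delta method on the FA side (the Jacobian of the alr signature w.r.t.
  each species' consumed alr profile propagates `Σ_s` into the predator
  covariance). The delta-method covariance was checked against Monte
  Carlo (relative error ~1% at the default within-species spread); the
  remaining approximation is a second-order mean shift. This mode is
  recommended for population-level work and is used in the validation
  experiments.
* `mean`: consumed profiles replaced by species means; the consumed-prey
  variability is absorbed by the residual covariance. Fastest, widest
  approximation.

### Diet groupings

* population: one `π` with a symmetric Dirichlet(α) prior (α = 1).
* individual: `π_j` per predator with a hierarchical logistic-normal
  prior. The clr-normal formulation is degenerate (clr vectors sum to
  zero), so internally an orthonormal (n−1)-dimensional ilr basis is
  used; proportions are reported on output.
* linear: the ilr-scale mean of `π_j` is `X_j B` for a predator design
  matrix (regression/ANOVA-style questions, e.g. treatment contrasts).

### Priors and defaults

* `κ_{s,f} ~ Gamma(m²/v, rate m/v)` and `Φ_s ~ LogNormal` moment-matched
  to supplied means/variances; variance 0 pins the coefficient (the
  no-conversion baseline `κ ≡ 1`, `Φ ≡ 1` is the default when no tables
  are given).
* `μ_s ~ N(0, 10² I)` in alr space; SI means get `N(0, 1000²)` (per-mil
  scales are larger).
* Covariances are inverse-Wishart with `df = dim + 2` and scale
  `c·I`: `c = 0.1` for prey covariances (`sigma_prey_scale`) and
  `c = 0.01` for predator residuals (`sigma_resid_scale`). These are the
  "order of magnitude of the diagonal" knobs; with few predators the
  residual prior matters and may need adjustment.
* The linearized mode's residual floor variance has a wide log-normal
  prior centred on `sigma_resid_scale`.

## Sampling

The engine is adaptive Metropolis-within-Gibbs over parameter blocks:

* conjugate Gibbs draws where exact (prey covariances given means;
  latent-mode prey means given latents; hierarchical diet mean and
  covariance);
* conjugate *proposals* corrected by the non-conjugate factor
  (independence MH) where the predator factor breaks conjugacy (prey
  means in mean-prey/linearized modes, prey covariances in linearized
  mode) — the proposal is the exact conditional of the remaining factors,
  so the acceptance ratio reduces to the predator factor alone;
* adaptive random-walk Metropolis in unconstrained coordinates for the
  rest (ilr for simplexes, log for positives), with proposal scales tuned
  to ~0.25 acceptance during warmup and frozen afterwards; prey-mean
  blocks use the analytic conditional covariance as a preconditioner.

Two structural problems required special treatment, both classic MCMC
pathologies rather than implementation details:

* With `J` predators and `p−1` alr dimensions, `Σ_τ` is barely identified
  when `J ≤ p`, and its coupling with the residuals mixes glacially. In
  mean-prey and latent modes `Σ_τ` (and its SI analogue) is therefore
  integrated out against its inverse-Wishart prior, turning the predator
  factor into a matrix-t density. Latent updates then use sequential
  per-predator proposals with rank-1 updates of the residual Gram matrix.
* Diet proportions and latent consumed prey form a narrow ridge (given
  the latents, the data pin `π` tightly). Two involutive joint moves are
  mixed in: a `π` proposal that translates every latent row by the shift
  in the anchor-predicted predator signature (unit Jacobian; Metropolis
  over all affected factors), and a `γ` proposal with exactly
  compensating latent-SI translations. Even so, the latent mode at the
  reference scale needs long chains; the linearized mode reaches
  effective sample sizes an order of magnitude higher per iteration and
  is what the validation experiments use.

Defaults: 3 chains, 20,000 iterations, 50% warmup discarded. Chains are
initialized at sample moments (prey), uniform-jittered diets, and prior
means (coefficients), overdispersed by jittering in unconstrained
coordinates. Split-chain rank-normalized R̂ and autocorrelation-based ESS
(via ArviZ) are computed after every run; R̂ > 1.1 is flagged prominently.
Runs are bit-reproducible from the seed.

Validation of the machinery: the sampler reproduces known targets
(standard normal, Dirichlet — which also exercises the ilr Jacobian
`√p·Ππ_i`, verified against finite differences); the full model posterior
was checked against brute-force oracles on small instances (fine-grid
posterior with fixed nuisance parameters, TV ≈ 0.02; Monte-Carlo
marginalization over latents and residual covariances, agreement within
MC error).

## FA selection

Gas chromatography yields more FAs than a Bayesian model can carry
comfortably. FAs are ranked by their contribution to among-species
separation under constrained ordination: principal coordinates of
Euclidean distances on clr-transformed profiles constrained by species
membership — which, the distance being Euclidean in clr space, reduces to
an SVD of the species-fitted clr matrix. Per-FA contributions are
eigenvalue-weighted squared loadings summed over the (≤ n_species − 1)
constrained axes, normalized to sum to one; alternatives (e.g. plain
squared loadings) are a one-line change and users comparing them should
report which they used. Selection adds FAs greedily in contribution order
until a cumulative among-source variance target (default 0.75) is reached,
subject to a cap (default 20) on the condition number of the species-mean
proportion matrix re-closed on the subset — the collinearity guard: prey
sources with nearly collinear mean signatures make the mixing problem
ill-conditioned no matter how much variance the FAs span. If no subset of
at least two FAs satisfies the cap, the best two are returned with a
warning.

## Synthetic data

The generator mirrors the model's own assumptions, which is exactly what
it is for: validating that the estimation machinery recovers known truth
under the model. Species alr-mean profiles sit at the vertices of a
regular simplex scaled by a single `separation` knob (pairwise distance
in alr units); within-species variability is isotropic normal in alr
space (`within_sd`, default 0.4); SI means are separated analogously in
per-mil units around a (δ¹³C, δ¹⁵N)-like baseline. Predators draw diets
(fixed vector, per-predator Dirichlet with an evenness parameter, or an
explicit per-predator table for feeding trials), consume individual prey
items drawn from the species distributions, and their signatures follow
the mixing equations plus residual noise. Optional knobs: per-predator
conversion-coefficient noise (gamma-distributed around `κ_true`), a
collinearity parameter pulling one species' mean toward a convex
combination of two others, and a mode confining among-species variation
to exactly `k` FAs (a zero-sum clr subspace) for variable-selection
studies.

The reference scenario is 3 prey species × 30 samples, 12 FAs, 2
isotopes, 10 predators, diet (0.2, 0.3, 0.5), separation 2.0 — separated
enough to discriminate sources readily while leaving visible
within-species variability. What the generator does *not* emulate:
measurement error distinct from biological variability, correlated
within-species FA structure, zeros from detection limits, diet
heterogeneity in time, or prey libraries that miss a true source. Passing
recovery tests on these simulations therefore shows the inference is
correct under the model's assumptions, not that the model is right for
any particular field dataset.

## Validation experiment sizes

The automated experiments (tests and `scripts/acceptance.py`) use: 20
replicate joint fits of the reference scenario (2 chains × 1,200
iterations, linearized mode) for recovery and coverage; 20 matched
joint/FA-only pairs (8 FAs, 20 samples, 8 predators) for the uncertainty
reduction; sensitivity grids of 3 levels × 10 replicates (4 species, 10
FAs, 15 samples, 8 predators, 600 iterations) for the separation and
conversion-noise directions; 50 prey-library replicates for selection
recall; and a 4,000-point grid posterior against 2 × 20,000 MCMC
iterations for the grid-oracle check. These sizes give stable pass/fail
behaviour while keeping the full suite in the tens of minutes on one CPU.

## Known limitations

* The latent-prey mode is the faithful model but mixes slowly at high FA
  counts; treat its defaults as a starting point and watch R̂. The
  linearized mode carries a small second-order bias toward even diets.
* Conversion coefficients are identified only relatively; comparing `κ`
  across studies requires the same normalization.
* Posterior means of proportions near 0 or 1 are biased toward the
  interior (an interval-scale fact, not a bug); report intervals, not
  just point estimates, for uneven diets.
* The SI fractionation model is an input (priors), not estimated from
  isotope mass balance here.
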
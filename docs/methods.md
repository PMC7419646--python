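# Methods

This note documents the models, the samplers, the synthetic-data generator,
and the numerical choices behind `beanmet`, in the order the pipeline runs.

## Trial data and derived traits

The canonical input is a long plot-level CSV keyed by
(genotype, environment, N level, block) carrying raw measurements: seed and
shoot dry biomass of the sampled plants, seed and shoot N percentages,
harvested seed mass with its moisture and area, and the N applied to the
plot. Missing measurements are empty cells and propagate as missing trait
values — never as zeros — so traits measured in only a subset of
environments are handled by per-trait missingness rather than separate
tables.

Derived traits:

| trait | definition | units |
|---|---|---|
| SY | mass · (100 − moist)/(100 − 13) · 10⁴/area | kg ha⁻¹ at 13% moisture |
| Prot | seed N% × 6.25 | % |
| HI | seed/(seed + shoot) | fraction in [0, 1] |
| plant N | seed·seedN% + shoot·shootN% (÷100) | g |
| NUpE | plant N / N applied | ratio |
| NUtE | seed biomass / plant N | ratio |
| NUsE | NUpE × NUtE = seed biomass / N applied | ratio |

HI is seed over total above-ground biomass: that is the definition the
reported magnitudes (≈ 0.46) and the biological reading ("fraction of
biomass allocated to seed") support, although field protocols sometimes
state the complementary ratio. The efficiency ratios are computed in
consistent grams; the conventional display units (mg g⁻¹, g mg⁻¹, g g⁻¹)
are treated as labels. Scalar trait functions raise domain errors;
the table-level `derive_all` downgrades per-cell violations to missing
values with a logged count, so one corrupt plot cannot abort an analysis.

## Chains, HPD intervals, Geweke

Every sampler returns a `Chain` (named draws plus total/burn-in/thinning
metadata). Inference is uniform across modules:

* **HPD interval** — the empirical shortest interval: over the sorted draws,
  the contiguous window of ⌈level·n⌉ draws with minimal width, ties broken
  by the smallest lower endpoint. Deterministic, and verified in the tests
  against an exhaustive window scan. Density estimation is deliberately
  avoided.
* **Significance conventions** — an effect is significant iff its HPD
  interval excludes zero, with a zero endpoint counting as overlap; two
  estimates differ iff their HPD intervals share no point, with a shared
  endpoint counting as overlap. Fixing the boundary cases makes every call
  bit-for-bit reproducible.
* **Geweke diagnostic** — z = (m̄₁ − m̄₂)/√(ŝ₁ + ŝ₂) comparing the first 10%
  with the last 50% of a chain, where ŝ are spectral-density-at-zero
  estimates of the segment-mean variances. S(0) is estimated by an
  autoregressive fit (Yule–Walker/Levinson–Durbin, order chosen by AIC up
  to 10·log₁₀ n), the estimator the reference implementation of this
  diagnostic uses. A Bartlett lag-window estimator was evaluated first and
  rejected: its bias and variance inflate the |z| > 1.96 rate on iid chains
  to ≈ 10%, whereas the AR estimator keeps it at the nominal 5% (measured
  3.5–7% across 200-replicate batches). Fits log a warning when |z| ≥ 1.96
  on the monitored parameters (μ, σ²_ε, and λ₁ for BAMMI) rather than
  failing.

Chains are single and long (the analyses this package reproduces ran one
chain per fit); multi-chain R̂ is out of scope.

## Hierarchical G×N×E models and DIC

The plot model is
y = μ + g + b(within experiment) + e + n + ge + gn + en + gen + ε with
environment (e), nitrogen (n) and e×n fixed, everything else random, and
four presets: full (all interactions), G×N only, G×E only, and additive
null; the fixed e×n term appears only in the full model, and blocks share a
single variance across experiments.

Sampling is collapsed-free conjugate Gibbs. Because each observation
belongs to exactly one level of a factor, all levels of one factor are
conditionally independent given the rest and are updated as a vectorized
block. Priors: N(0, 10¹⁰) on μ and the fixed-effect levels;
scaled-inverse-χ²(ν₀ = 0.002, s₀² = 1) on every variance component —
vague but proper, and configurable. Fixed-effect blocks are recentred to
sum-to-zero each sweep with the removed means folded into μ (exact double
centring for e×n), so μ is the overall mean and the likelihood is
untouched; random effects keep their shrinkage prior unconstrained.

DIC uses the deviance conditional on all sampled effects (the lowest-level
focus, matching the MCMC software family these models are usually fit
with): mean deviance is accumulated during sampling, D(θ̄) plugs in the
posterior means of every parameter, p_D is their difference, and
DIC = D(θ̄) + 2p_D. Differences are read on the 5/10 scale with inclusive
bounds.

Two honest limitations, visible in the tests: (i) with only two nitrogen
levels the three-way g×e×n effects are partially confounded with g×e, so
σ²_gen is weakly identified — at the 40×4×2×4 design and 20k iterations the
posterior mean lands within 50% of truth for the typical seed (median over
seeds), but an occasional chain is trapped near zero by the variance
funnel; (ii) variance-component mixing is slow enough that model-selection
runs should not go below ~10k iterations.

Desk-scale defaults are 20,000/5,000/5 (total/burn-in/thin); the
publication-scale 1,000,000/500,000/5 is available as a preset.

## Genetic progress

Trait values are averaged to genotype × N-level means (this is the response
unit that makes the regression intercept equal the overall N-level trait
mean), then regressed on release year by conjugate Gibbs with the predictor
centred at the mean year. Percent progress per year is computed per draw as
100·β₁/β₀ and summarized with mean and HPD; the plug-in ratio of posterior
means is exposed separately because the two legitimately differ in the last
printed decimal. The per-draw version requires all β₀ draws on one side of
zero, otherwise the percent is undefined and an error is raised. The
high-vs-low-N comparison is the HPD-overlap rule on the two β₁ intervals.

## Correlations and PCA

The correlation posterior comes from the bivariate normal with a
Jeffreys-type prior, under which Σ | data ~ inverse-Wishart(n − 1, S); the
correlation is transformed per draw. Measured type-I rate at n = 160 is
≈ 4–6% against the nominal 5%, and power at ρ = 0.5 is ≈ 100%. A
heavier-tailed bivariate-t alternative (df = 4, scale-mixture Gibbs) is
available behind `robust=True`; the default stays normal.

PCA standardizes the variables (the six traits have incommensurate units),
samples the covariance of the standardized data from its inverse-Wishart
posterior, and eigendecomposes every draw. Two label-switching hazards are
handled per draw: components are ordered by eigenvalue, and eigenvector
signs are aligned by dot product against the sample-eigenvector reference —
without this, HPD intervals on loadings and scores are meaninglessly
inflated by sign flips. A known small-sample feature: the ordered
per-draw eigenvalue fractions are biased apart relative to the sample
eigenvalues (order-statistics effect); the posterior mean converges to the
sample spectrum as n grows (within 2% at n = 5000 in the tests).

## BAMMI

The cell-mean table (genotype × composite environment, where a composite
environment is site-season × N, e.g. `LD17-HN`) is modelled as
y = μ + τᵢ + δⱼ + Σₖ λₖ αᵢₖ γⱼₖ + ε with λ₁ ≥ … ≥ λₜ > 0 and the singular
vectors unit-norm, mutually orthogonal and orthogonal to the 1-vector.
Priors: N(0, 10¹⁵) on μ, τ, δ and each λₖ (positive-truncated), spherical
uniform on the corrected subspace for αₖ and γₖ, scaled-inverse-χ² on σ²_ε.

Full conditionals: Gaussian for μ/τ/δ (τ, δ recentred to sum-to-zero each
sweep, means folded into μ); zero-truncated Gaussian for λₖ (the regressor
αₖγₖᵀ has unit Frobenius norm, so the conditional variance is
(1/σ² + 1/σ²_λ)⁻¹); von Mises–Fisher for αₖ with direction ∝ R⁽ᵏ⁾γₖ·λₖ/σ²
— sampled in an orthonormal basis of the null space of [1, α₋ₖ] and
embedded back, which enforces the constraints exactly — and symmetrically
for γₖ. The sampler is initialized at the classical AMMI solution (SVD of
the double-centred table).

Identifiability devices the model does not pin down, applied per sweep or
retained draw: descending relabeling of the (λ, α, γ) triples restores the
order restriction; joint sign flips of (αₖ, γₖ) toward a running
posterior-mean reference remove the sign ambiguity (a joint flip leaves
λₖαₖγₖᵀ unchanged). The sampler operates on cell means without cell-count
weighting, appropriate for the balanced designs generated here.

Downstream calls: per-component interaction share λₖ²/Σλ²; biplot scores in
the symmetric scaling (√λₖ·αₖ, √λₖ·γₖ), whose per-draw products exactly
reconstruct the multiplicative term; favorable/unfavorable environments by
the sign of the δ HPD; genotype stability = both Comp.1/Comp.2 score HPDs
containing zero; specific adaptation = positively aligned posterior-mean
score vectors between a non-stable genotype and an interaction-contributing
environment. t defaults to 2 — the two axes the stability semantics use —
and is configurable up to min(g, a) − 1.

One behaviour worth knowing: a single-cell perturbation of size c is not a
rank-1 pattern localized to that cell; after double centring it leaks
~c/g into every other genotype's leading score, so with a large planted
signal a few bystander genotypes are correctly called non-stable. The
tests encode this expectation.

## Synthetic trials

The generator emulates the study design the analyses assume: 40 cultivars
with release years 1970–2017, 4 site-seasons × 2 N levels × 4 blocks
(1,280 plots), RCBD. Seed yield is built additively with genotype effects
carrying a linear release-year trend, fixed environment and nitrogen
effects, a rank-t multiplicative G×E structure (orthonormal sum-to-zero
singular vectors — the same identification the BAMMI sampler assumes, so
recovery needs only sign alignment), iid G×N and G×E×N effects, iid
blocks, and Gaussian plot noise. Default magnitudes are anchored to the
published trial: μ = 2,309.65 kg ha⁻¹ with N effects ±185.97 (high/low
means 2,495.61/2,123.68), residual SD 520 kg ha⁻¹, progress slope
13.1 kg ha⁻¹ yr⁻¹, λ = (300, 150) for the planted interaction; E×N fixed
effects default to zero since no reference values exist.

Measured columns are back-solved from target trait values rather than
simulated through crop chemistry: moisture is fixed at 13% so SY round-trips
exactly; Prot/HI/NUpE/NUtE are drawn per genotype × N level from a
correlated Gaussian (correlation matrix defaulting to published low-N
estimates projected to the nearest positive-definite matrix) plus small
plot jitter, then seed/shoot biomass and N percentages are solved so the
trait derivation reproduces the targets bit-for-bit. Targets are clipped to
boxes (HI ∈ [0.25, 0.60], NUtE ∈ [1.6, 4.0], Prot ∈ [10, 30],
NUpE ∈ [0.03, 1.5]) chosen so the back-solved shoot N% always lands in
(0, 100); at the default means and SDs the clipping is essentially never
active. Negative yields (a ~4σ event at the defaults) are clamped at zero
to respect mass non-negativity.

What the generator does **not** emulate: spatial field trends, non-Gaussian
noise, heteroscedastic environments, missing-at-random patterns beyond the
optional restriction of the N-assay traits to selected environments, or any
real chemistry linking yield to the N traits. Passing recovery tests
therefore demonstrates correctness of the samplers under their own model
class, not robustness to real-data pathologies.

## Problem sizes and numerical choices

* Desk-scale MCMC defaults: 20,000/5,000/5; the model-selection suite runs
  a 20 × 3 × 2 × 2 design at 12,000/4,000/4 over 10 replicate seeds, sizes
  at which the DIC ranking properties are stable (full model wins on
  full-simulated data; nothing beats the null by ≥ 5 on null data).
* Truncated-normal draws use inverse-CDF sampling with a fallback to the
  untruncated draw when the truncation point is ≥ 8 SDs below the mean.
* von Mises–Fisher concentration κ → 0 falls back to the uniform sphere;
  1-dimensional subspaces use the exact two-point conditional.
* All samplers are seeded through `numpy.random.default_rng`; multi-fit
  drivers spawn child seeds via `SeedSequence`, and identical seeds give
  bit-identical chains on a given platform (row order of the input is
  canonicalized first).
* The sum-to-zero recentring used everywhere folds removed means into the
  parent term, so fitted values — hence likelihoods and DIC — are invariant
  to the identification step.

## Known limitations

* σ²_gen (and variance components generally) mix slowly under vague priors;
  occasional chains stick near zero. Parameter expansion would fix this and
  is not implemented.
* DIC is conditional-focus; marginal-focus DIC would give different p_D.
* No missing-cell imputation in BAMMI; unbalanced tables must be completed
  upstream or analyzed otherwise.
* The Bayesian correlation default is the normal model; the t option exists
  but genotype-mean panels of size ~40 rarely need it.
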
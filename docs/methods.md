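# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Allometric models

Both responses (tree height, mean crown radius; metres) are modelled
against DBH (cm) on the log10 scale.

**Linearized power law.**
log10(y_ij) ~ Normal(α_j + β_j · log10(DBH_ij), σ).
α_j is the log10 dimension at DBH = 1 cm — "how big is a sapling of this
species" — and β_j the dimensionless scaling exponent.  Intercepts are
deliberately *not* centred on the mean log DBH, so that α_j keeps this
interpretation at small trunk sizes.

**Asymptotic form.**
log10(y_ij) ~ Normal(a_j · (1 − exp(−b_j · DBH_ij)), σ), a two-parameter
saturating family in which a_j is the log10 asymptotic size and b_j > 0
the per-cm approach rate.  Height–diameter relationships are commonly fit
with either family; the package fits both and compares them by WAIC.
Several saturating parameterizations exist in the literature; this one was
chosen for being the simplest that keeps log-normal residuals and a
two-parameter species-level hierarchy exactly parallel to the power form.

**Hierarchy and priors.**  Species pairs (α_j, β_j) — (a_j, log b_j) for
the asymptotic form — follow a bivariate normal with means (μ_α, μ_β), SDs
(sd_α, sd_β) and correlation ρ.  Priors:

| parameter | prior | default | why |
|---|---|---|---|
| μ_β (power) | Normal | mean 0.75 (height) / 0.70 (crown), SD 0.5 | global angiosperm scaling exponents; SD wide so data dominate |
| μ_α (power) | Normal(0, 1) | — | ~1 m at 1 cm DBH, very diffuse on log10 scale |
| μ_a, μ_log b (asymptotic) | Normal | 1.3 / 0.6 and log 0.15, SD 1 / 0.5 | ~20 m canopy height, ~4 m crown radius, gentle saturation |
| sd_α, sd_β | half-Normal(1) | — | weakly informative on log10 scales |
| ρ | Uniform(−1, 1) | — | no prior direction for intercept–slope covariance |
| σ | half-Normal(1) | — | residual log10 SD ≪ 1 in practice |

A single σ is shared across species (species-specific residual scales are
not identifiable with ~10–25 trees per species).

## Sampler

The sampler is MCMC with blocks chosen for the model's structure:

* (α_j, β_j) | rest — exact conjugate bivariate-normal Gibbs draw, batched
  over species with the analytic 2×2 Cholesky.
* (μ_α, μ_β) | rest — conjugate Gibbs.
* (sd_α, sd_β, ρ, σ) — random-walk Metropolis on log/identity scales
  against the *collapsed* likelihood p(y | μ, Σ, σ) with the species pairs
  integrated out analytically (Woodbury identity on per-species sufficient
  statistics).  Collapsing removes the scale–parameter funnel that makes
  centred Gibbs samplers mix slowly when sd_β is small — exactly the
  regime here, since interspecific slope variation is tiny.  The species
  pairs are redrawn from their full conditional immediately afterwards,
  making the pair (collapsed scale move, conditional redraw) a valid
  blocked update.
* Asymptotic form: the likelihood is nonlinear in (a_j, log b_j), so the
  species pairs move by joint per-species random-walk Metropolis (three
  sweeps per iteration; this is the slowest-mixing block), with the same
  hyper-mean Gibbs and scale Metropolis structure.

Step sizes adapt multiplicatively toward 44% (scalar) / 30% (joint)
acceptance during warmup only; the post-warmup chain is time-homogeneous.
Defaults are four chains of 20,000 iterations with 10,000 warmup,
mirroring common practice for this model class; all replicate experiments
and the acceptance script use a desk-scale profile of four chains × 2,000
iterations (warmup 1,000), which the convergence diagnostics support for
this model size (J = 14, N ≈ 210; split R-hat ≤ 1.05, bulk ESS in the
hundreds).  Split R-hat above 1.05 raises a warning and is flagged in the
returned convergence report and the `convergence.csv` table — never
silently.

**WAIC.**  lppd computed by log-sum-exp over draws; p_waic as the
pointwise sample variance (denominator S − 1); waic = −2(lppd − p_waic),
reported with its pointwise decomposition.

## Phylogenetic comparative layer

Independent contrasts use Felsenstein's pruning algorithm.  Because the
algorithm is linear in tip values, the package precomputes a (J−1) × J
contrast matrix per tree and applies it to thousands of posterior draws at
once.  Two determinism choices matter:

* **Sign convention.**  Kendall's tau between two contrast sets is not
  invariant to flipping one node's contrast sign in only one variable, so
  the child order at every node is fixed by the lexicographically smallest
  descendant tip label and applied identically to every variable.  Results
  are therefore independent of newick child order; a different (equally
  valid) convention could change individual tau values on real data.
* **Polytomies are rejected**, not silently resolved: resolution changes
  the contrasts.

Kendall's tau is the tau-b (tie-corrected) estimator by explicit pair
enumeration, vectorized over stacks of draws; it equals tau-a when no
ties occur.

## Posterior propagation

Per analysis, n_samples = 10,000 posterior draws are resampled uniformly
with replacement (a seeded choice; with enough retained draws an
each-draw-exactly-once mode is available).  Per draw, the species vector
of interest (intercepts, slopes, or expected dimensions
10^(α_j + β_j·log10 D) at each reference diameter D ∈ {1, 3, …, 19} cm) is
contrasted on the tree and correlated with each trait's contrasts; the tau
distribution is summarized by its median and equal-tailed 2.5/97.5
percentiles (linear interpolation).  Expected dimensions are plug-in
means of the log-scale model (no residual noise added).  For the
height–crown coupling the two independently fit posteriors are paired by
draw index (with an independent-resampling option); pairing is a
convention, not information.

Traits enter as fixed species means — no trait measurement uncertainty is
propagated.  No multiple-testing adjustment is applied across the trait ×
target grid.

**What the interval means.**  The 95% interval reflects *posterior
uncertainty in the allometric parameters only*.  It is not a confidence
interval for tau under species resampling: with J species there are only
J − 1 contrasts, and the finite-community dispersion of a null tau
(SD ≈ 0.2 at J = 14) is not part of the propagated uncertainty.
Consequently, when the posterior is tight (small residual SD, many trees
per species) the interval concentrates near the realized tau of that one
community, and a trait with no generating relationship can still yield an
interval excluding zero.  The replicate experiments in the test suite
measure this directly: under zero coupling, intercept-target intervals
contain zero in only ~60% of combinations at the default study
conditions, while slope-target intervals (whose posteriors are noisier
than the tiny interspecific slope variation) contain zero ~99% of the
time.  Users should read "excludes zero" as "robust to allometric
parameter uncertainty", not as a community-level significance test.

## Synthetic-data generator

The generator emulates the study design the pipeline targets:

* **Phylogeny**: pure-birth (Yule) tree, unit rate, ultrametric, default
  14 tips — the comparative layer needs only a binary tree with branch
  lengths.  A user-supplied newick can replace it.
* **Traits**: six species-mean traits (leaf %N, leaf %P, wood density,
  leaf area, SLA, seed mass) evolved by independent Brownian motion, with
  roots at field-typical values (e.g. wood density 0.6 g/cm³) and rates
  sized for ~10–15% tip spread, keeping values positive and the contrast
  assumption exactly true.  Traits are generated and contrasted on the
  same scale (no log transform) so tests exercise the assumption they
  state; an analysis-side log10 option exists for real data.
* **Allometric parameters**: (α_j, β_j) from the same bivariate-normal
  hyperstructure the model assumes — height (0.45, 0.75), crown
  (−0.35, 0.70), sd_α = 0.10, sd_β = 0.025, ρ = −0.3 — i.e. clear
  intercept variation, nearly common slopes.  Standardized traits shift
  intercept means linearly; default couplings (height: wood density
  −0.06; crown: wood density +0.05, seed mass +0.05, leaf %P −0.04)
  reproduce the qualitative architecture–trait syndrome of interest at a
  magnitude (~0.5 × sd_α) that is detectable only sometimes at J = 14 —
  the power experiments use 2 × sd_α.
* **Individuals**: 15 trees per species; log10 DBH ~ Normal(0.9, 0.35)
  (≈ 1–30 cm, spanning the 1–19 cm reference grid); residual SD 0.05 on
  the log10 response.  One DBH per tree is shared by both responses;
  response noise is independent.  A BM rate of zero is accepted as the
  degenerate diffusion (tips equal the root); negative rates are errors.

Everything is reproducible from a single seed via spawned seed sequences.
What the generator does **not** emulate: measurement error in DBH,
within-species trait variation, non-ultrametric or birth–death trees,
Ornstein–Uhlenbeck trait evolution, crown asymmetry, and any empirical
DBH distribution — so passing tests demonstrate correctness of the
machinery under the stated model, not robustness to these violations.

## Numerical choices and degenerate inputs

* Percentile summaries use linear interpolation throughout.
* Crown radius from two perpendicular measurements is their arithmetic
  mean; single-measurement records are accepted.
* Records missing a response are dropped from that response's model only
  (count logged); every validation failure names its row or species.
* Writers emit 12-significant-digit floats; written tables reread to
  equality at that precision, and one global seed makes all output tables
  byte-identical across reruns on the same platform.
* All-tied vectors make tau-b undefined and raise; trees must be strictly
  binary with positive branch lengths.

## Known limitations

* The collapsed-Metropolis sampler is exact but single-threaded; very
  large communities (hundreds of species) would want a gradient-based
  engine.
* The asymptotic form's per-species Metropolis block occasionally leaves
  split R-hat slightly above 1.05 at the desk-scale profile on hard
  datasets; the flag is surfaced and longer chains resolve it.
* Tau credible intervals quantify posterior, not community-sampling,
  uncertainty (see above) — with few species this distinction is large.
* WAIC is reported per model on the same observations; no standard error
  of the WAIC difference is computed.
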
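# allotrait

Hierarchical Bayesian tree allometry and its phylogenetically controlled
correlation with functional traits.

## The scientific problem

In closed-canopy forests, species differ in tree *architecture* — how tall
they are and how wide their crowns spread at a given trunk diameter — and
those differences are expected to line up with the classic
acquisitive-to-conservative functional trait spectrum: dense-wooded,
heavy-seeded, low-leaf-nutrient species (shade-tolerant, survival-oriented)
should be shorter and broader-crowned at a given diameter than light-wooded
fast growers racing toward the canopy.

`allotrait` implements the full analysis chain for testing this with field
allometry measurements, species-mean trait tables and a dated phylogeny:

1. **Allometric models.** For each response y (height in m, crown radius in
   m) against DBH (trunk diameter at 130 cm, in cm), a partial-pooling
   model on the log10 scale:

   log10(y_ij) ~ Normal(α_j + β_j · log10(DBH_ij), σ),
   (α_j, β_j) ~ BVN((μ_α, μ_β), Σ),

   with Σ decomposed into SDs and a correlation, slope priors centred on
   global angiosperm scaling exponents (0.75 height, 0.70 crown), and an
   alternative saturating form log10(y) = a_j·(1 − e^(−b_j·DBH)).  Both are
   fit by an in-package MCMC (conjugate Gibbs + adaptive Metropolis, with a
   collapsed update for the hypercovariance) and compared by WAIC.
   α_j is the log10 dimension at DBH = 1 cm; β_j the scaling exponent.

2. **Phylogenetic comparative layer.** Felsenstein's independent contrasts
   with a deterministic sign convention, and Kendall's tau-b between
   contrast sets — so trait–architecture correlations are not inflated by
   shared ancestry.

3. **Posterior propagation.** The posterior of the species parameters is
   resampled (10,000 draws by default); per draw, tau is computed between
   trait contrasts and contrasts of intercepts, slopes, or expected
   dimensions at reference diameters 1, 3, …, 19 cm; the tau distribution
   is summarized as median and equal-tailed 95% interval.

4. **Synthetic data.** Because suitable field data are rarely public, a
   generator produces Yule phylogenies, Brownian-motion traits, and
   trait-coupled allometric parameters with known truth, which is how the
   whole pipeline is validated.

## Worked example

Simulate a 14-species community in which denser-wooded species are
markedly shorter at a given diameter (intercept coupling −0.2 log10 units
per trait SD, i.e. twice the interspecific intercept SD), then fit and
correlate:

```python
import numpy as np
import allotrait as at

cfg = at.SyntheticConfig(
    seed=7,
    height=at.AllometryRegime(0.45, 0.75, residual_sd=0.02,
                              coupling={"wood_density": -0.2}),
)
ds = at.generate_dataset(cfg)
draws = at.fit_hierarchical(
    ds.observations, at.ModelSpec(response="height"),
    at.McmcSettings.reduced(seed=101),
)
print(round(float(np.median(draws.mu_beta)), 3))   # 0.747
print(draws.convergence["max_rhat"] < 1.05)        # True

tab = at.sample_parameter_correlations(
    draws, ds.traits, ds.phylogeny, n_samples=10_000, seed=1
)
row = tab[(tab.target == "intercept") & (tab.trait == "wood_density")].iloc[0]
print(round(row.median_tau, 3), round(row.lo95, 3),
      round(row.hi95, 3), bool(row.excludes_zero))  # -0.59 -0.641 -0.513 True
```

The hyper-slope posterior median 0.747 recovers the generating scaling
exponent (0.75), and the wood-density × height-intercept Kendall
correlation is strongly negative with a 95% interval that excludes zero —
the injected architecture–trait coupling is detected despite posterior
uncertainty and phylogenetic control.  (With the default generator's
milder coupling of −0.06, the realized correlation in a single 14-species
community is often too weak to exclude zero; the replicate experiments in
the test suite quantify exactly this.)

The same stages are available from the shell:

```bash
allotrait pipeline --seed 1 --out runs/demo            # simulate -> fit -> correlate
```

which writes `allometry.csv`, `traits.csv`, `tree.nwk`, posterior draws,
`waic.csv`, `parameter_tau.csv` (6 traits × {intercept, slope} × 2
responses), `sizeclass_tau.csv` (6 traits × 10 diameters × 2 responses)
and `coupling_tau.csv` (height–crown tau per diameter).

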
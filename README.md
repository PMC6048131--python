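# domfit

Co-estimation of the **distribution of fitness effects (DFE)** and the
**dominance coefficient h** of new nonsynonymous mutations from site
frequency spectra (SFS), by jointly fitting data from an **outcrossing** and
a **highly selfing** population — together with a mechanistic
**expression-cost model** that predicts why strongly deleterious mutations
tend to be recessive.

## Who this is for

Population geneticists with folded synonymous/nonsynonymous SFS from a
species pair with contrasting mating systems (the motivating case is the
outcrosser *Arabidopsis lyrata* and the selfer *A. thaliana*), who want to
ask: are new deleterious amino-acid mutations additive (h = 0.5), uniformly
(non-)recessive, or does recessivity deepen with deleteriousness?

## The model

In a single outcrossing population, h and the DFE are confounded: the SFS
depends mainly on the heterozygous effect h·s. In a selfer, genotypes are
homozygous, so the SFS depends on s alone; at inbreeding coefficient F the
diffusion of allele frequency p has per-generation moments

    M(p) = s p(1-p) { (1-F)[h + (1-2h)p] + F },
    V(p) = p(1-p)(1+F) / (2N),

and at F = 1 both become h-independent: the selfing diffusion is the additive
one with an effective selection coefficient **s_e = 2s** at the drift-matched
effective size. Combining both populations therefore makes (DFE, h)
identifiable.

`domfit` models the DFE of |s| as a gamma distribution (optionally plus a
neutral point mass) and dominance with a nested menu:

* additive: h = 0.5 (0 parameters)
* constant: h = h_const (1)
* h–s relationship: h = 1 / (1/θ_intercept − θ_rate·s) (2), with a logistic
  alternative; more deleterious mutations may be more recessive.

Expected spectra come from a Poisson random field diffusion solver under a
piecewise-constant demography fitted to the synonymous SFS (θ_NS = 2.31·θ_S),
accelerated by a spline-refined lookup table over (N_e·s, h). Entries are
scored with the Poisson likelihood; the two populations' log-likelihoods add
(composite likelihood), and nested models are compared by likelihood-ratio
tests with χ² references (df = parameter difference). Uncertainty comes from
a Poisson-resampling bootstrap; per-gene-category estimates are compared by
Z-scores with Bonferroni correction.

A Wright–Fisher machinery (exact transition-matrix chain and a per-mutation
forward simulator) provides an independent oracle for the solver and
generates synthetic datasets for calibration and power studies.

## Worked example

`examples/04_simulate_and_infer.py` simulates a two-species dataset under a
known h–s relationship (θ_intercept = 0.5, θ_rate = 48,000, so an s = −0.001
mutation has h ≈ 0.02) and refits the model menu:

```
outcrossing: 5772 synonymous, 6950 nonsynonymous segregating sites
inbreeding: 1480 synonymous, 894 nonsynonymous segregating sites
additive  LL =   -129.537  params = shape=0.9504, mean_s=0.000338
constant  LL =    -72.098  params = shape=0.2906, mean_s=0.006931, h_const=0.006867
inverse   LL =    -68.726  params = shape=0.302, mean_s=0.004948, theta_intercept=0.1791, theta_rate=2.039e+04
h-s relationship vs constant h: Lambda = 6.75, df = 1, p = 9.40e-03
fitted dominance of an s = -0.001 mutation: h = 0.0385 (truth 0.0204 under the generating model)
```

Additivity is overwhelmingly rejected, the h–s relationship beats even a
free constant h, and the dominance of moderately deleterious mutations is
recovered — at 1/50 of the genome-wide mutation rate. At realistic θ the
relationship-vs-constant test statistics are in the hundreds (see
`domfit.calibration.run_power_analysis`). The other examples cover spectrum
handling, expected SFS under selection/selfing, the grid cache, and the
expression-cost model.

The `domfit` CLI wraps the same library calls:
`domfit simulate`, `domfit fit-demog`, `domfit build-grid`, `domfit fit`
(full pipeline; `--paper-scale` restores 1000 optimizer starts and a
1000×1000 grid), `domfit bootstrap`, `domfit lrt`, `domfit calibrate-lrt`,
`domfit compare-categories`.

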
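# Methods

## Model

`domfit` treats the entries of a site frequency spectrum as independent
Poisson counts whose means are given by the forward diffusion of allele
frequency under mutation, drift, selection, dominance and inbreeding (the
Poisson random field, PRF). With selection coefficient s (genotype fitnesses
1, 1+hs, 1+s), dominance h, inbreeding coefficient F and population size N,
the per-generation mean and variance of the frequency change are

    M(p) = s p(1-p){(1-F)[h + (1-2h)p] + F},      V(p) = p(1-p)(1+F)/(2N).

Two limits organise the method. For an outcroser (F = 0) the SFS is mainly
informative about the product h·s; for a full selfer (F = 1) both moments are
h-independent and equal the additive outcrossing model with selection doubled
(s_e = 2s) at the drift-matched effective size, so the selfing SFS reads out
s directly. Jointly fitting one DFE and one h–s relationship to both
populations therefore breaks the h–DFE confounding that defeats
single-population inference.

The DFE of new nonsynonymous mutations is Gamma(shape, scale) over |s|
(deleterious only; optional neutral point mass p_neutral). Dominance models,
in nesting order: additive (h = 0.5), constant h, and the inverse h–s
relationship h = 1/(1/θ_intercept − θ_rate·s), with a logistic alternative
h = θ_intercept(1+e^(−θ_offset))/(1+e^(θ_rate|s|−θ_offset)). θ_intercept is
the dominance of an s = 0 mutation, θ_rate the decay of h with
deleteriousness. As θ_rate → 0 the inverse model becomes constant h; constant
h = 0.5 is additive.

Inference is staged, as is standard for PRF selection inference: (1) fit a
piecewise-constant size history (up to three epochs) to the synonymous SFS by
maximum Poisson likelihood, profiling the mutation-rate scale θ_S
analytically; (2) conditional on it, precompute expected spectra over a
(γ = N_e·s, h) lattice; (3) maximise the composite likelihood (sum of the two
populations' Poisson log-likelihoods of the nonsynonymous SFS) over DFE and
dominance parameters with θ_NS fixed at 2.31·θ_S; (4) compare nested
dominance models by Λ = 2ΔLL against χ² with df equal to the difference in
free parameter count; (5) quantify uncertainty by Poisson-resampling
bootstrap (B = 20 by default), reporting SE and normal-approximation 95% CIs
(mean ± 1.96·SE; percentile intervals are unstable at B = 20), and compare
parameters between gene categories with Z = Δestimate/√(SE_a² + SE_b²),
Bonferroni-corrected.

## Numerical machinery

**Diffusion solver.** The forward equation is discretised with a
Scharfetter–Gummel (exponentially fitted) finite-volume scheme on a frequency
grid crowded toward 0 and 1 (400 interior points by default), which remains
stable in the advection-dominated near-lethal regime. Mutational influx
enters at the lowest interior node at rate θ/(2x₁) — per-generation influx
scales with the current epoch's relative size. The ancestral equilibrium is a
direct tridiagonal solve; post-ancestral epochs use implicit Euler steps
(dt = 1e-3 in units of 2N_anc generations). Expected sample spectra are
binomial-weighted trapezoid integrals with analytic boundary limits, with
optional Richardson extrapolation over two grid resolutions (on by default).
At neutrality and constant size the solver reproduces θ/i to ~1e-7; under a
bottleneck it matches coalescent (msprime branch-length) expectations within
Monte-Carlo error and the exact Wright–Fisher chain within ~1%.

**Scaled selection.** γ ≡ N_e·s with N_e the ancestral effective size,
everywhere. For F = 1 the solver routes through (2γ, h = 0.5, F = 0); the
general-F path is kept and exercised by tests. The drift-effective size of a
selfing population of N individuals is N/2.

**Grid cache.** Spectra are tabulated on a 50×20 coarse lattice — γ
exponential from −N_e (lethal) to −1e-4 (effectively neutral), h linear on
[0,1] — and refined by a two-pass per-frequency cubic spline (γ pass in
log|γ|, then h), by default to 1000×1000 (desk-scale pipelines use 400×200).
Splines interpolate log spectra: entries fall off exponentially in γ·h toward
the lethal-recessive corner, where linear-space splines are badly wrong
(probe errors >100%) while log-space splines stay within ~1% over the regions
carrying appreciable expected counts. Negative values (impossible in log
space, retained as a guard) are clamped to zero and counted. Grids carry
provenance (demography, n, F, N_e) and a content hash; stale caches are
rebuilt, never silently served. |γ| < 1e-4 is served by the
demography-matched neutral spectrum.

**DFE integration.** One-dimensional trapezoid quadrature along the grid's γ
nodes with gamma-density weights and h = f(s) per node (nearest grid h);
gamma mass beyond −N_e is assigned to the lethal boundary cell (per-
generation s cannot fall below −1), mass above the neutral cutoff plus
p_neutral to the neutral spectrum. Against a brute-force Riemann sum at 10×
node density with directly solved spectra, per-entry agreement is ≤1%.

**Optimisation.** Nelder–Mead on transformed coordinates (log for shape and
mean |s|, logit for θ_intercept/h_const/p_neutral, θ_rate/1e4), multi-start
uniform (log-uniform for scales) within bounds: shape ∈ [0.01, 5],
E|s| ∈ [1e-6, 0.2], θ_intercept ∈ (0, 1], |θ_rate| ≤ 1e7, h ∈ [0, 1]. An
explicit initial simplex (step 0.3, polish passes at 0.05 and 0.01) is used
because the default simplex collapses at zero-valued coordinates. The model
menu is fitted with an upward pass (each model warm-started from the nested
optima) and a downward pass (each null re-polished from the richer models'
DFE estimates), keeping fitted LLs monotone in model size. Desk default is
20–50 starts; `--paper-scale` restores 1000.

**Two-sided decay rate during fitting.** θ_rate is searched on a two-sided
interval (h clipped to [0, 1]; the public h-of-s API still requires
θ_rate ≥ 0). With a one-sided bound the additive and constant-h nulls sit on
the boundary of the h–s model's parameter space and Λ would follow a
½χ²(1)+½χ²(2) mixture rather than χ²(2); the two-sided search keeps the null
interior so the usual χ² reference applies. A fitted negative rate simply
reads "no decay detected".

## Simulator and study conditions

`wf_sim` provides (a) an exact Wright–Fisher transition-matrix chain
(deterministic selection step q' = q + M(q), multinomial genotype sampling at
inbreeding F, influx θ/2 per generation at one copy — one homozygous
individual for F = 1 — and hypergeometric sampling of the final generation),
used as the independent oracle for the diffusion solver; and (b) a forward
simulator of synthetic datasets with per-mutation s from the gamma DFE and
h = f(s), optionally beta-noised around f(s) with fixed sd (0.1), through the
fitted demography. Fixation and loss drop mutations from the tally. Because
the chain uses the diffusion's first-order selection response, the F = 1
equivalence to the additive chain at s_e = 2s is exact rather than O(s²).

Two engines generate data. The literal per-mutation engine evolves each
mutation by binomial sampling (burn-in 10·2N generations before the epochs).
The "field" engine exploits the fact that independently evolving mutations
arriving as a Poisson process make the sampled SFS entries exactly
independent Poisson variables around the chain-expected spectrum, so it draws
Poisson counts around chain expectations: distributionally identical to the
per-mutation engine for the independent-sites model (the tests verify the
engines agree), and fast enough for genome-scale θ. Chain expectations are
memoised at unit θ (counts are linear in θ).

Simulations are downscaled 50-fold: population size divided by 50, s
multiplied by 50, θ unchanged, which preserves the diffusion limit;
per-generation s is clamped at −1 (such mutations die immediately at either
scale). The desk-scale study conditions, fixed once: genome-wide
θ_S/θ_NS = 131,600/304,000 (outcrossing) and 41,800/96,600 (selfing), with a
10× smaller profile mirroring per-category data; nominal ancestral
N_e = 20,000 (downscaled chain size 400 — large enough that chain-vs-
diffusion discreteness does not distort LRT calibration); three-epoch
demography (ν, T) = (0.25, 0.2), (1.2, 0.05) for both species; gamma DFE
shape 0.3, mean |s| = 0.005; inverse h–s relationship with θ_intercept = 0.5
and θ_rate = 48,000 (h(−0.001) ≈ 0.0204); samples of 22 allele copies
(outcrossing) and 12 single-copy accessions (selfing, one copy per
effectively homozygous individual); μ = 7e-9.

## Calibration design

The null calibration (100 additive-truth replicates at the 10×-reduced
profile) and the power study (20 h–s-truth replicates at genome θ) condition
the dominance-model fits on the generating demography and on the probability
limit of the θ_S plug-in estimate (θ̂ computed from the expected, not the
resampled, synonymous spectrum). The reason is statistical, not
computational: θ̂_S carries Poisson sampling noise (~1/√θ relative), which
propagates into the fixed θ_NS = 2.31·θ̂_S; that scale error cannot be
absorbed by the shared DFE for both species at once but is partially
absorbable by dominance parameters, inflating Λ by a θ-independent ~0.5–1
with occasional large excursions — for any implementation of the full
plug-in pipeline. The χ² reference applies to the dominance LRT proper,
conditional on the conditioning stage; bootstrap uncertainty, which does
re-estimate θ (and optionally the demography) per resample, is the mechanism
that propagates first-stage noise into reported intervals. Under these
conditions Λ(additive vs constant) and Λ(additive vs h–s) pass KS tests
against χ²(1) and χ²(2), no null statistic approaches 30, and the h–s model
beats constant h in 20/20 power replicates (Λ ≈ 230–440) with fitted
h(−0.001) within [0.013, 0.031] of the true 0.0204.

## Expression-cost model of dominance

Fitness as a function of expression level x is
f(x) = (x + intercept·scale)(1 − c·x)/(x + scale): saturating benefit, linear
cost c per unit expression (c = 0.001 throughout; conclusions are robust to
c). `intercept` is fitness at zero expression (≈1: dispensable gene);
`scale` is the expression at half-maximal benefit (large: many molecules
needed, e.g. structural proteins; small: catalytic proteins). The optimum is
x_opt = √(scale·c·(1−intercept)(1+scale·c))/c − scale, which exists for
1 − intercept > c·scale; genes without a positive optimum are recorded as
s = 0 and excluded from dominance statistics. A loss-of-function mutation
has x = x_opt/2 when heterozygous and x = 0 when homozygous, giving
|s| = (f(x_opt) − f(0))/f(x_opt) and
h = (f(x_opt) − f(x_opt/2))/(f(x_opt) − f(0)); s is reported ≤ 0 to match the
inference modules' sign convention. The gene-ensemble simulation (5000
genes, intercept ~ U(0.9, 1), scale ~ |N(0.1, 0.1)|) predicts h < 0.5 for
every selected gene, a negative |s|–h correlation, and mean h increasing in
scale; evaluating at 80% of optimal expression changes h by < 0.15. The
model is compared with the SFS-based estimates qualitatively; it is not
coupled into the likelihood.

## What the synthetic data do and do not show

The generator realises the PRF's own assumptions: free recombination
(independent sites), no linkage or background-selection structure beyond
what the fitted demography absorbs, neutral synonymous sites, a strictly
gamma DFE, a deterministic h(s) (except in the beta-noise variant), and
F exactly 1 in the selfer. Passing calibration and recovery tests therefore
demonstrates correctness and statistical behaviour of the estimator under
its model, not robustness to linked selection, mis-specified DFEs, partial
selfing, or ancestral-state and annotation errors in real data. Desk-scale
ensemble sizes (100 null replicates, 20 power replicates, B ≈ 6–20
bootstrap resamples, 50×20 → 400×200 grids, tens of optimizer starts) are
the package's default compromise between resolution and turnaround; every
knob scales up by configuration (`--paper-scale`).

## Known limitations

* No positive selection (the γ axis is deleterious-plus-neutral only) and no
  divergence-based quantities.
* The composite likelihood ignores the (negligible for strongly diverged
  pairs) correlation of allele frequencies between species, and the Poisson
  field ignores within-genome linkage, so composite LL differences are not
  exact likelihood ratios on real data.
* Partial selfing (0 < F < 1) is supported by the solver and the oracle but
  the two-population pipeline assumes F ∈ {0, 1}.
* θ̂ plug-in noise slightly over-disperses full-pipeline LRT statistics at
  small data sizes (see Calibration design); bootstrap intervals, not the χ²
  asymptotics, are the honest uncertainty statement for real data.
* The dominance of nearly neutral mutations (|s| ≲ 5e-4) is weakly
  identified; simulations with dominance variance show θ_intercept biased
  upward, so estimates of h near s = 0 should not be over-read.
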
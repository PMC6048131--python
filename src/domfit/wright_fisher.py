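"""Exact Wright-Fisher computations and forward simulation of SFS data.

Two engines live here.

``wf_exact_expected_sfs`` is a brute-force oracle: the full Wright-Fisher
Markov chain on allele counts, with selection entering through the
first-order (diffusion) mean change q' = q + M(q) and multinomial genotype
sampling at inbreeding coefficient F, run to stationarity of the segregating
mass under a steady mutational influx.  It validates the diffusion solver
independently of it.

``forward_simulate`` generates synthetic spectra the way a per-mutation
forward simulator does: selection coefficients drawn from a gamma DFE,
dominance set by an h-s relationship (optionally with beta-distributed noise),
allele counts evolving by Wright-Fisher sampling through a piecewise-constant
size history, and a final-generation sample tallied into folded spectra.  Two
interchangeable engines are provided: a literal per-mutation engine, and a
"field" engine that exploits the fact that independently evolving mutations
arriving as a Poisson process yield sampled SFS entries that are exactly
independent Poisson draws around the chain-expected spectrum.  The two are
distributionally identical; the field engine makes genome-scale mutation
rates affordable.

Downscaling convention: simulations run at a population size reduced by
``downscale`` (default 50) with per-generation selection coefficients
multiplied by the same factor and theta left unchanged, which preserves the
diffusion limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .dfe import GammaDFE, HSRelationship, discretize_gamma_dfe
from .diffusion import DemographicModel
from .errors import ResourceLimitError
from .sfs import SpectrumCounts, fold, write_spectrum

__all__ = [
    "SimulationConfig",
    "wf_exact_expected_sfs",
    "forward_simulate",
    "generate_fixtures",
]

# Desk-scale study conditions: genome-wide theta values for the
# selfing ("inbreeding") and outcrossing populations, and a nominal
# ancestral effective size downscaled 50-fold for simulation.
GENOME_WIDE_THETAS = {
    "syn_inbreeding": 41_800.0,
    "nonsyn_inbreeding": 96_600.0,
    "syn_outcrossing": 131_600.0,
    "nonsyn_outcrossing": 304_000.0,
}
DEFAULT_NE = 20_000.0
DEFAULT_DEMOGRAPHY = DemographicModel(((0.25, 0.2), (1.2, 0.05)))


@dataclass
class SimulationConfig:
    """Conditions of one two-species simulation study.

    Defaults reproduce the genome-wide study conditions: paper-scale theta
    values, a three-epoch size history shared by both species, a gamma DFE of
    new nonsynonymous mutations, an inverse h-s relationship with intercept
    0.5 and decay rate chosen so that h(-0.001) ~ 0.02, and 50-fold
    downscaling of the nominal ancestral effective size of 20,000.
    """

    demography: DemographicModel = field(default_factory=lambda: DEFAULT_DEMOGRAPHY)
    thetas: dict = field(default_factory=lambda: dict(GENOME_WIDE_THETAS))
    dfe: GammaDFE = field(default_factory=lambda: GammaDFE(0.3, 5e-3 / 0.3))
    hs: HSRelationship = field(
        default_factory=lambda: HSRelationship("inverse", theta_intercept=0.5,
                                               theta_rate=48_000.0))
    N_e: float = DEFAULT_NE
    downscale: float = 50.0
    n_sample_outcrossing: int = 22
    n_sample_inbreeding: int = 12
    h_noise_sd: float | None = None
    n_dfe_bins: int = 60
    replicates: int = 1
    seed: int = 0
    engine: str = "field"  # "field" or "per_mutation"

    def __post_init__(self):
        if self.downscale < 1:
            raise ValueError("downscale must be >= 1")

    @property
    def N_scaled(self) -> float:
        return self.N_e / self.downscale

    def theta_scaled(self, scale: float) -> "SimulationConfig":
        """Config with every theta divided by ``scale`` (e.g. 10 for the
        small-category profile)."""
        return replace(self, thetas={k: v / scale for k, v in self.thetas.items()})


# -- exact chain oracle --------------------------------------------------


def _genotype_freqs(q, F):
    """Genotype frequencies at allele frequency q with inbreeding F."""
    het = 2.0 * q * (1.0 - q) * (1.0 - F)
    aa = q * q + F * q * (1.0 - q)
    AA = 1.0 - het - aa
    return AA, het, aa


def _post_selection_freq(q, s, h, F):
    """One generation of the diffusion mean change, clipped to [0, 1]."""
    G = (1.0 - F) * (h + (1.0 - 2.0 * h) * q) + F
    return np.clip(q + s * q * (1.0 - q) * G, 0.0, 1.0)


def _allele_count_pmf_rows(qs, N, F):
    """Rows of P(allele count k' | post-selection frequency q) for N diploid
    individuals drawn multinomially from the inbreeding-equilibrium genotype
    frequencies; k' = 2 * n_aa + n_het ranges over 0..2N."""
    if F == 0.0:
        k = np.arange(2 * N + 1)
        return stats.binom.pmf(k[None, :], 2 * N, qs[:, None])
    AA, het, aa = _genotype_freqs(qs, F)
    out = np.zeros((len(qs), 2 * N + 1))
    for r, (pAA, phet, paa) in enumerate(zip(AA, het, aa)):
        # pmf of 2*X_aa + X_het, (X_*) ~ Multinomial(N): coefficients of
        # (pAA + phet z + paa z^2)^N via exponentiation by squaring
        poly = np.array([pAA, phet, paa])
        result = np.array([1.0])
        n = N
        while n:
            if n & 1:
                result = np.convolve(result, poly)
            poly = np.convolve(poly, poly)
            n >>= 1
        out[r, :len(result)] = result
    return out


def _transition_matrix(N_from, N_to, s, h, F):
    """Transition from allele counts of 2*N_from copies to 2*N_to copies."""
    q = np.arange(2 * N_from + 1) / (2.0 * N_from)
    q1 = _post_selection_freq(q, s, h, F)
    return _allele_count_pmf_rows(q1, N_to, F)


def _segregating_mass(P, theta):
    """Stationary expected occupancy of transient states 1..2N-1 under influx
    theta/2 per generation at count 1."""
    K = P.shape[0] - 1
    Ptt = P[1:K, 1:K]
    rhs = np.zeros(K - 1)
    rhs[0] = theta / 2.0
    m = np.linalg.solve(np.eye(K - 1) - Ptt.T, rhs)
    return m


def _sampling_matrix(two_N, n):
    """H[k, i] = P(i copies in a sample of n | k of two_N in the population),
    hypergeometric sampling without replacement."""
    k = np.arange(two_N + 1)[:, None]
    i = np.arange(n + 1)[None, :]
    return stats.hypergeom.pmf(i, two_N, k, n)


def wf_exact_expected_sfs(N: int, s: float, h: float, F: float, n: int,
                          theta: float,
                          demography: DemographicModel | None = None
                          ) -> SpectrumCounts:
    """Expected unfolded SFS from the full Wright-Fisher Markov chain.

    ``N`` is the number of diploid individuals in the ancestral population
    (2N + 1 allele-count states); for F = 1 the drift-effective size is N/2.
    Mutations enter at allele count 1 at rate theta/2 per generation; the
    expected segregating mass is the stationary solution of the chain (then
    propagated through any post-ancestral epochs), and sampling of n allele
    copies is hypergeometric.
    """
    if N > 500:
        raise ResourceLimitError(
            f"N={N} requires a {2 * N + 1}^2 transition matrix; limit is 500")
    if N < 2 or n < 2 or n > 2 * N:
        raise ValueError("need 2 <= n <= 2N and N >= 2")
    demography = demography or DemographicModel()
    if F >= 1.0:
        # track mutant homozygotes: mutations enter as one homozygous
        # individual (frequency 1/N of copies), the chain is the additive
        # allele chain on N copies, and accessions are sampled one copy each
        if n > N:
            raise ValueError("for F=1 at most N accessions can be sampled")
        return wf_exact_expected_sfs_large(N, s, h, 1.0, n, theta, demography)
    P = _transition_matrix(N, N, s, h, F)
    m = _segregating_mass(P, theta)
    m = np.concatenate([[0.0], m, [0.0]])
    N_cur = N
    # epoch durations are in units of 2 * N_e,anc generations; the influx of
    # new mutations per generation scales with the current size (nu * theta/2)
    two_Ne_anc = 2 * N
    for nu, T in demography.epochs:
        N_next = max(int(round(nu * N)), 2)
        gens = max(int(round(T * two_Ne_anc)), 1)
        influx = (theta / 2.0) * (N_next / N)
        P_cross = _transition_matrix(N_cur, N_next, s, h, F)
        m = m @ P_cross
        m[0] = m[-1] = 0.0
        m[1] += influx
        if gens > 1:
            P_in = _transition_matrix(N_next, N_next, s, h, F)
            for _ in range(gens - 1):
                m = m @ P_in
                m[0] = m[-1] = 0.0
                m[1] += influx
        N_cur = N_next
    H = _sampling_matrix(2 * N_cur, n)
    e = m @ H
    return SpectrumCounts(e[1:n], n, folded=False,
                          label=f"wf N={N} s={s:g} h={h:g} F={F:g}")


# -- chain-expected spectra under a DFE (field engine) -------------------


def _chain_dfe_expected_unit(config: SimulationConfig, species: str,
                             additive: bool = False,
                             constant_h: float | None = None):
    """Unit-theta expected unfolded (syn, nonsyn) spectra for one species
    from the WF chain, integrating the gamma DFE over discretised selection
    classes.  Expected counts are linear in theta, so callers scale these by
    the actual theta values."""
    selfing = species == "inbreeding"
    F = 1.0 if selfing else 0.0
    n = (config.n_sample_inbreeding if selfing
         else config.n_sample_outcrossing)
    Ne_scaled = config.N_scaled
    # chain individuals: drift-effective size Ne needs N individuals = Ne
    # (outcrossing) or 2 Ne (selfing, where N_e = N/2)
    N_ind = int(round(Ne_scaled)) if not selfing else int(round(2 * Ne_scaled))

    syn = wf_exact_expected_sfs_large(N_ind, 0.0, 0.5, F, n, 1.0,
                                      config.demography)
    gammas, masses = discretize_gamma_dfe(config.dfe, config.N_e,
                                          config.n_dfe_bins)
    nonsyn = np.zeros(n - 1)
    for g, w in zip(gammas, masses):
        s_nominal = g / config.N_e
        s_chain = max(g / Ne_scaled, -1.0)  # near-lethal clamp after rescale
        if selfing or additive:
            h = 0.5
        elif constant_h is not None:
            h = constant_h
        else:
            h = config.hs.h_of_s(s_nominal)
        e = wf_exact_expected_sfs_large(N_ind, s_chain, h, F, n, 1.0,
                                        config.demography)
        nonsyn += w * e.counts
    if config.dfe.p_neutral > 0:
        nonsyn += config.dfe.p_neutral * syn.counts
    return syn.counts, nonsyn


def wf_exact_expected_sfs_large(N, s, h, F, n, theta, demography):
    """As :func:`wf_exact_expected_sfs` but without the brute-force size cap
    (F restricted to {0, 1} so binomial rows apply); used by the field engine.
    Transition matrices are sparsified (binomial rows are effectively banded)
    so large populations stay affordable."""
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    if F not in (0.0, 1.0):
        raise ValueError("field engine supports F of exactly 0 or 1")
    two_N = 2 * N if F == 0.0 else N  # selfing chain tracks individuals
    s_eff, h_eff = (s, h) if F == 0.0 else (s, 0.5)

    def chain(K_from, K_to):
        # For F = 1 the individuals chain is the additive allele chain
        P = _binomial_chain(K_from, K_to, s_eff, h_eff, F)
        P[P < 1e-15] = 0.0
        return sparse.csr_matrix(P)

    P = chain(two_N, two_N)
    K = two_N
    Ptt = P[1:K, 1:K]
    rhs = np.zeros(K - 1)
    rhs[0] = theta / 2.0
    ident = sparse.identity(K - 1, format="csc")
    m = spsolve((ident - Ptt.T).tocsc(), rhs)
    m = np.concatenate([[0.0], m, [0.0]])
    two_Ne_anc = two_N  # drift-effective copies: 2N (F=0) or N (F=1)
    K_cur = two_N
    for nu, T in demography.epochs:
        K_next = max(int(round(nu * two_N)), 4)
        gens = max(int(round(T * two_Ne_anc)), 1)
        influx = (theta / 2.0) * (K_next / two_N)  # current-size mutation rate
        m = m @ chain(K_cur, K_next)
        m[0] = m[-1] = 0.0
        m[1] += influx
        if gens > 1:
            P_in = chain(K_next, K_next)
            for _ in range(gens - 1):
                m = m @ P_in
                m[0] = m[-1] = 0.0
                m[1] += influx
        K_cur = K_next
    H = _sampling_matrix(K_cur, n)
    e = m @ H
    return SpectrumCounts(e[1:n], n, folded=False)


def _binomial_chain(K_from, K_to, s, h, F):
    """Binomial transition rows on K copies (alleles for F=0, individuals for
    F=1, where the haploid-like chain with fitness 1+s per mutant individual
    realises M = s q (1-q), V = q(1-q)/N)."""
    q = np.arange(K_from + 1) / K_from
    q1 = _post_selection_freq(q, s, h, F)
    k = np.arange(K_to + 1)
    return stats.binom.pmf(k[None, :], K_to, q1[:, None])


# -- forward simulation --------------------------------------------------


def _beta_noise_h(rng, mean_h, sd):
    """Per-mutation dominance from a beta law with the given mean and sd,
    clipped to [0.001, 0.999] when the moment solution is infeasible."""
    mean_h = np.clip(mean_h, 1e-3, 1 - 1e-3)
    var = sd * sd
    cap = mean_h * (1.0 - mean_h)
    var = np.minimum(var, 0.95 * cap)
    nu = cap / var - 1.0
    a, b = mean_h * nu, (1.0 - mean_h) * nu
    return np.clip(rng.beta(a, b), 0.001, 0.999)


def _simulate_class_per_mutation(rng, config, species, theta, neutral):
    """Literal per-mutation Wright-Fisher simulation of one site class."""
    import warnings

    if theta / 2.0 < 1.0:
        warnings.warn(
            f"theta={theta:g} implies fewer than one new mutation per "
            "generation; spectra will be sparse", stacklevel=3)
    selfing = species == "inbreeding"
    F = 1.0 if selfing else 0.0
    n = (config.n_sample_inbreeding if selfing
         else config.n_sample_outcrossing)
    Ne = config.N_scaled
    K_anc = int(round(2 * Ne))  # copies tracked (alleles F=0, individuals F=1)
    two_Ne_anc = K_anc
    burn = 10 * K_anc
    schedule = [(K_anc, burn)]
    for nu, T in config.demography.epochs:
        schedule.append((max(int(round(nu * K_anc)), 4),
                         max(int(round(T * two_Ne_anc)), 1)))
    counts = np.zeros(0, dtype=np.int64)
    svals = np.zeros(0)
    hvals = np.zeros(0)
    K_cur = K_anc
    for K_next, gens in schedule:
        influx = (theta / 2.0) * (K_next / K_anc)  # current-size mutation rate
        for _ in range(gens):
            q = counts / K_cur
            q1 = _post_selection_freq_arr(q, svals, hvals, F)
            counts = rng.binomial(K_next, q1)
            seg = (counts > 0) & (counts < K_next)
            counts, svals, hvals = counts[seg], svals[seg], hvals[seg]
            n_new = rng.poisson(influx)
            if n_new:
                if neutral:
                    s_new = np.zeros(n_new)
                    h_new = np.full(n_new, 0.5)
                else:
                    s_nom = -config.dfe.sample(rng, n_new)
                    s_new = np.maximum(s_nom * config.downscale, -1.0)
                    h_mean = config.hs.h_of_s(s_nom)
                    if config.h_noise_sd:
                        h_new = _beta_noise_h(rng, h_mean, config.h_noise_sd)
                    else:
                        h_new = h_mean
                    if selfing:
                        h_new = np.full(n_new, 0.5)
                counts = np.concatenate([counts, np.ones(n_new, dtype=np.int64)])
                svals = np.concatenate([svals, s_new])
                hvals = np.concatenate([hvals, h_new])
            K_cur = K_next
    # final-generation sample of n copies, hypergeometric per mutation
    sampled = rng.hypergeometric(counts, K_cur - counts, n)
    seg = (sampled > 0) & (sampled < n)
    hist = np.bincount(sampled[seg], minlength=n)[1:n].astype(float)
    return fold(SpectrumCounts(hist, n, folded=False,
                               label=f"{species} {'syn' if neutral else 'nonsyn'}"))


def _post_selection_freq_arr(q, s, h, F):
    G = (1.0 - F) * (h + (1.0 - 2.0 * h) * q) + F
    return np.clip(q + s * q * (1.0 - q) * G, 0.0, 1.0)


_field_cache: dict = {}


def expected_spectra_for_config(config: SimulationConfig, additive=False,
                                constant_h=None):
    """Chain-expected folded spectra per species for a configuration.

    The expensive chain solves are memoised at unit theta (expected counts
    are linear in theta), so configurations differing only in their theta
    profile share one computation.
    """
    key = (
        config.demography.epochs,
        config.dfe.shape, config.dfe.scale, config.dfe.p_neutral,
        config.hs.form, config.hs.theta_intercept, config.hs.theta_rate,
        config.hs.theta_offset, config.hs.h_const,
        config.N_e, config.downscale, config.n_sample_outcrossing,
        config.n_sample_inbreeding, config.n_dfe_bins, additive, constant_h,
    )
    if key not in _field_cache:
        _field_cache[key] = {
            sp: _chain_dfe_expected_unit(config, sp, additive=additive,
                                         constant_h=constant_h)
            for sp in ("outcrossing", "inbreeding")
        }
    out = {}
    for sp, (syn_unit, ns_unit) in _field_cache[key].items():
        n = (config.n_sample_inbreeding if sp == "inbreeding"
             else config.n_sample_outcrossing)
        syn = fold(SpectrumCounts(config.thetas[f"syn_{sp}"] * syn_unit, n,
                                  folded=False, label=f"{sp} syn"))
        ns = fold(SpectrumCounts(config.thetas[f"nonsyn_{sp}"] * ns_unit, n,
                                 folded=False, label=f"{sp} nonsyn"))
        out[sp] = (syn, ns)
    return out


def forward_simulate(config: SimulationConfig, additive: bool = False,
                     constant_h: float | None = None):
    """Simulate per-replicate (synonymous, nonsynonymous) folded spectra for
    both species.

    Returns a list of ``replicates`` dicts keyed by species name, each value a
    ``(syn, nonsyn)`` pair of folded :class:`SpectrumCounts`.

    ``additive=True`` forces h = 0.5 everywhere; ``constant_h`` forces a fixed
    dominance coefficient; otherwise dominance follows ``config.hs`` (with
    optional beta noise of sd ``config.h_noise_sd`` in the per-mutation
    engine).
    """
    rng = np.random.default_rng(config.seed)
    out = []
    if config.engine == "field":
        exp = expected_spectra_for_config(config, additive=additive,
                                          constant_h=constant_h)
        for _ in range(config.replicates):
            rep = {}
            for sp, (syn_e, ns_e) in exp.items():
                syn = syn_e.copy()
                syn.counts = rng.poisson(syn_e.counts).astype(float)
                ns = ns_e.copy()
                ns.counts = rng.poisson(ns_e.counts).astype(float)
                rep[sp] = (syn, ns)
            out.append(rep)
        return out
    if config.engine != "per_mutation":
        raise ValueError(f"unknown engine {config.engine!r}")
    cfg = config
    if additive:
        cfg = replace(config, hs=HSRelationship("additive"))
    elif constant_h is not None:
        cfg = replace(config, hs=HSRelationship("constant", h_const=constant_h))
    for _ in range(cfg.replicates):
        rep = {}
        for sp in ("outcrossing", "inbreeding"):
            syn = _simulate_class_per_mutation(
                rng, cfg, sp, cfg.thetas[f"syn_{sp}"], neutral=True)
            ns = _simulate_class_per_mutation(
                rng, cfg, sp, cfg.thetas[f"nonsyn_{sp}"], neutral=False)
            rep[sp] = (syn, ns)
        out.append(rep)
    return out


def generate_fixtures(profile: str, seed: int, out_dir,
                      desk_scale_divisor: float = 1.0,
                      config: SimulationConfig | None = None) -> dict:
    """Write a bundle of four .fs spectra (syn/nonsyn x two species) plus a
    YAML manifest.

    ``profile`` is ``genome_wide`` (paper-scale thetas) or ``small_category``
    (all thetas 10 times smaller, mirroring the size of per-category data);
    ``desk_scale_divisor`` further divides every theta for quick runs.
    """
    import os

    import yaml

    if profile not in ("genome_wide", "small_category"):
        raise ValueError(f"unknown profile {profile!r}")
    config = config or SimulationConfig()
    scale = desk_scale_divisor * (10.0 if profile == "small_category" else 1.0)
    cfg = replace(config.theta_scaled(scale), seed=seed, replicates=1)
    rep = forward_simulate(cfg)[0]
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for sp, (syn, ns) in rep.items():
        for cls, spec in (("syn", syn), ("nonsyn", ns)):
            name = f"{sp}_{cls}.fs"
            write_spectrum(spec, os.path.join(out_dir, name))
            paths[f"{sp}_{cls}"] = name
    manifest = {
        "profile": profile,
        "seed": seed,
        "thetas": dict(cfg.thetas),
        "theta_ratio_nonsyn_syn": {
            sp: cfg.thetas[f"nonsyn_{sp}"] / cfg.thetas[f"syn_{sp}"]
            for sp in ("outcrossing", "inbreeding")
        },
        "dfe": {"shape": cfg.dfe.shape, "scale": cfg.dfe.scale,
                "p_neutral": cfg.dfe.p_neutral},
        "hs": {"form": cfg.hs.form,
               "theta_intercept": cfg.hs.theta_intercept,
               "theta_rate": cfg.hs.theta_rate},
        "demography": cfg.demography.to_dict(),
        "N_e": cfg.N_e,
        "downscale": cfg.downscale,
        "files": paths,
    }
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
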
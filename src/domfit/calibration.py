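"""Simulation-based calibration and power analysis of the dominance LRTs.

These routines tie the forward simulator to the inference machinery: spectra
are simulated under a known dominance model at the study's theta magnitudes
(50-fold downscaled population, theta unchanged, selection rescaled), the
nested model menu is refit to each replicate conditional on the generating
demography, and the distribution of the likelihood-ratio statistic is
compared with its asymptotic chi-square reference (null calibration) or used
to count rejections (power).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .diffusion import expected_sfs
from .grid import build_coarse, refine
from .inference import DatasetBlock, fit_model_menu, lrt
from .sfs import fold
from .wright_fisher import SimulationConfig, forward_simulate

__all__ = ["grids_for_config", "make_blocks", "run_null_calibration",
           "run_power_analysis"]

_grid_cache: dict = {}
_unit_syn_cache: dict = {}


def grids_for_config(config: SimulationConfig, gamma_points: int = 50,
                     h_points: int = 20, refine_to=(400, 200),
                     pts: int = 300):
    """Refined (gamma, h) grids for both species of a simulation config,
    conditional on its (true) demography; memoised."""
    key = (config.demography.epochs, config.N_e,
           config.n_sample_outcrossing, config.n_sample_inbreeding,
           gamma_points, h_points, refine_to, pts)
    if key not in _grid_cache:
        grids = {}
        for sp, n, F in (("outcrossing", config.n_sample_outcrossing, 0.0),
                         ("inbreeding", config.n_sample_inbreeding, 1.0)):
            g = build_coarse(config.demography, n, config.N_e, F,
                             gamma_points, h_points, pts=pts)
            grids[sp] = refine(g, *refine_to)
        _grid_cache[key] = grids
    return _grid_cache[key]


def _unit_syn_expected(config: SimulationConfig, n: int):
    key = (config.demography.epochs, n)
    if key not in _unit_syn_cache:
        _unit_syn_cache[key] = fold(expected_sfs(
            config.demography, 0.0, 0.5, 0.0, n, 1.0, pts=300, extrap=True))
    return _unit_syn_cache[key]


def make_blocks(config: SimulationConfig, replicate: dict,
                theta_from: str = "replicate",
                expected: dict | None = None) -> list:
    """Inference dataset blocks for one simulated replicate, conditioning on
    the generating demography.

    ``theta_from="replicate"`` re-estimates theta_syn from the replicate's
    synonymous SFS (the full plug-in procedure; its sampling noise propagates
    into the fixed nonsynonymous mutation rate).  ``theta_from="expected"``
    instead evaluates the plug-in estimator at its probability limit (the
    simulator's expected synonymous spectrum), which conditions the dominance
    tests on the conditioning stage and is the setting in which their
    chi-square asymptotics apply.
    """
    grids = grids_for_config(config)
    blocks = []
    for sp in ("outcrossing", "inbreeding"):
        syn, nonsyn = replicate[sp]
        unit = _unit_syn_expected(config, syn.sample_size)
        um = ~syn.mask
        if theta_from == "expected":
            source = expected[sp][0]
            theta_hat = source.counts[um].sum() / unit.counts[um].sum()
        else:
            theta_hat = syn.counts[um].sum() / unit.counts[um].sum()
        mult = config.thetas[f"nonsyn_{sp}"] / config.thetas[f"syn_{sp}"]
        blocks.append(DatasetBlock(
            name=sp, syn=syn, nonsyn=nonsyn, demography=config.demography,
            theta_syn=theta_hat, F=1.0 if sp == "inbreeding" else 0.0,
            N_e=config.N_e, grid=grids[sp], nonsyn_multiplier=mult))
    return blocks


def run_null_calibration(replicates: int = 100, seed: int = 0,
                         theta_divisor: float = 10.0,
                         config: SimulationConfig | None = None,
                         n_starts: int = 4) -> dict:
    """Additive-truth LRT calibration.

    Simulates ``replicates`` datasets under h = 0.5 at the 10x-reduced theta
    profile (the size of per-category data), refits the nested menu to each,
    and KS-tests Lambda(additive vs constant) against chi-square(1) and
    Lambda(additive vs h-s) against chi-square(2).  The dominance tests are
    conditioned on the generating demography and mutation rate (the
    probability limit of the conditioning stage); see the methods note.
    """
    base = config or SimulationConfig()
    cfg = base.theta_scaled(theta_divisor)
    cfg = cfg.__class__(**{**vars(cfg), "seed": seed,
                           "replicates": replicates, "engine": "field"})
    from .wright_fisher import expected_spectra_for_config

    expected = expected_spectra_for_config(cfg, additive=True)
    reps = forward_simulate(cfg, additive=True)
    lam1, lam2, lam_ch = [], [], []
    for i, rep in enumerate(reps):
        blocks = make_blocks(cfg, rep, theta_from="expected",
                             expected=expected)
        fits = fit_model_menu(blocks, n_starts=n_starts, seed=seed + 13 * i)
        lam1.append(lrt(fits["additive"], fits["constant"]).lambda_)
        lam2.append(lrt(fits["additive"], fits["inverse"]).lambda_)
        lam_ch.append(lrt(fits["constant"], fits["inverse"]).lambda_)
    lam1, lam2 = np.array(lam1), np.array(lam2)
    return {
        "lambda_const": lam1,
        "lambda_hs": lam2,
        "lambda_const_vs_hs": np.array(lam_ch),
        "ks_p_df1": stats.kstest(lam1, stats.chi2(1).cdf).pvalue,
        "ks_p_df2": stats.kstest(lam2, stats.chi2(2).cdf).pvalue,
        "type1_df2_at_05": float(np.mean(stats.chi2.sf(lam2, 2) < 0.05)),
        "config": cfg,
    }


def run_power_analysis(replicates: int = 20, seed: int = 0,
                       config: SimulationConfig | None = None,
                       n_starts: int = 5) -> dict:
    """Power of the h-s relationship test and recovery of the fitted curve.

    Simulates under the inverse h-s relationship at the genome-wide theta
    profile (intercept 0.5, decay rate giving h(-0.001) ~ 0.02), tests the
    h-s model against constant h (df = 1), and records the fitted h at
    s = -0.001.
    """
    base = config or SimulationConfig()
    cfg = base.__class__(**{**vars(base), "seed": seed,
                            "replicates": replicates, "engine": "field"})
    from .wright_fisher import expected_spectra_for_config

    expected = expected_spectra_for_config(cfg)
    reps = forward_simulate(cfg)
    p_values, h_at_m3, lam = [], [], []
    for i, rep in enumerate(reps):
        blocks = make_blocks(cfg, rep, theta_from="expected",
                             expected=expected)
        fits = fit_model_menu(blocks, n_starts=n_starts,
                              seed=seed + 13 * i,
                              forms=("additive", "constant", "inverse"))
        t = lrt(fits["constant"], fits["inverse"])
        p_values.append(t.p_value)
        lam.append(t.lambda_)
        h_at_m3.append(float(fits["inverse"].relationship().h_of_s(-1e-3)))
    p_values = np.array(p_values)
    h_at_m3 = np.array(h_at_m3)
    return {
        "p_values": p_values,
        "lambda": np.array(lam),
        "h_at_minus_0.001": h_at_m3,
        "n_reject_05": int(np.sum(p_values < 0.05)),
        "n_h_below_0.1": int(np.sum(h_at_m3 < 0.1)),
        "true_h": float(base.hs.h_of_s(-1e-3)),
        "config": cfg,
    }
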
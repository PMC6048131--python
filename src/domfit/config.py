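"""Run configuration and the end-to-end inference driver.

``run_full_inference`` executes the whole workflow on a pair (or a single
population) of synonymous/nonsynonymous folded spectra: demographic fit on
the synonymous SFS, (gamma, h) grid build conditional on it, the nested
dominance-model fits, likelihood-ratio tests, and optional bootstrap
uncertainty — emitting a machine-readable report plus a plain-text log of
per-stage timings and seeds, so every reported number is reproducible from
the config alone.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass

import yaml

from .diffusion import ancestral_ne, fit_demography
from .grid import build_coarse, refine
from .inference import DatasetBlock, ModelSpec, bootstrap, fit_model_menu, lrt
from .sfs import read_spectrum

__all__ = ["DatasetConfig", "RunConfig", "run_full_inference"]


@dataclass
class DatasetConfig:
    """Paths and population context of one species' data."""

    name: str
    syn_path: str
    nonsyn_path: str
    F: float = 0.0
    family: str = "three_epoch"
    mu: float = 7e-9
    L_syn: float = 1e7
    nonsyn_multiplier: float = 2.31


@dataclass
class RunConfig:
    datasets: list
    out_dir: str = "domfit_run"
    forms: tuple = ("additive", "constant", "inverse")
    gamma_points: int = 50
    h_points: int = 20
    refine_points: tuple = (400, 200)
    solver_pts: int = 300
    n_starts: int = 20
    demog_starts: int = 8
    bootstrap_B: int = 0
    constrain_intercept: float | None = None
    p_neutral_free: bool = False
    shared_dfe: bool = True
    seed: int = 0
    paper_scale: bool = False

    def __post_init__(self):
        self.datasets = [d if isinstance(d, DatasetConfig)
                         else DatasetConfig(**d) for d in self.datasets]
        if self.paper_scale:
            self.n_starts = 1000
            self.refine_points = (1000, 1000)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "refine_points" in raw:
            raw["refine_points"] = tuple(raw["refine_points"])
        if "forms" in raw:
            raw["forms"] = tuple(raw["forms"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "out_dir", "gamma_points", "h_points", "solver_pts", "n_starts",
            "demog_starts", "bootstrap_B", "constrain_intercept",
            "p_neutral_free", "shared_dfe", "seed", "paper_scale")}
        d["forms"] = list(self.forms)
        d["refine_points"] = list(self.refine_points)
        d["datasets"] = [vars(ds).copy() for ds in self.datasets]
        return d


def run_full_inference(config: RunConfig) -> dict:
    """Demographic fits -> grid builds -> nested model fits -> LRTs
    (-> bootstrap).  Returns the report dict; writes ``report.json`` and
    ``run.log`` under ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines: list[str] = []

    def log(msg):
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        log_lines.append(line)

    def fail(stage, exc):
        log(f"stage {stage} FAILED: {exc!r}")
        _write_log(config, log_lines)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report: dict = {"config": config.to_dict(), "seed": config.seed,
                    "demography": {}, "fits": {}, "lrt": {}}
    blocks = []
    for i, ds in enumerate(config.datasets):
        t0 = time.time()
        try:
            syn = read_spectrum(ds.syn_path)
            nonsyn = read_spectrum(ds.nonsyn_path)
            demog, theta_syn, ll = fit_demography(
                syn, family=ds.family, n_starts=config.demog_starts,
                seed=config.seed + 100 * i, pts=config.solver_pts)
        except Exception as exc:  # noqa: BLE001 - report stage and abort
            fail(f"fit-demography[{ds.name}]", exc)
        N_e = ancestral_ne(theta_syn, ds.mu, ds.L_syn)
        report["demography"][ds.name] = {
            "epochs": [list(e) for e in demog.epochs],
            "theta_syn": theta_syn, "ll": ll, "N_e": N_e,
            "family": ds.family}
        log(f"demography[{ds.name}]: theta_syn={theta_syn:.6g} "
            f"N_e={N_e:.6g} LL={ll:.4f} ({time.time() - t0:.1f}s, "
            f"seed={config.seed + 100 * i})")
        t0 = time.time()
        try:
            g = build_coarse(demog, syn.sample_size, N_e, ds.F,
                             config.gamma_points, config.h_points,
                             pts=config.solver_pts)
            g = refine(g, *config.refine_points)
        except Exception as exc:  # noqa: BLE001
            fail(f"build-grid[{ds.name}]", exc)
        log(f"grid[{ds.name}]: {config.gamma_points}x{config.h_points} -> "
            f"{g.spectra.shape[0]}x{g.spectra.shape[1]} "
            f"({time.time() - t0:.1f}s)")
        blocks.append(DatasetBlock(
            name=ds.name, syn=syn, nonsyn=nonsyn, demography=demog,
            theta_syn=theta_syn, F=ds.F, N_e=N_e, grid=g,
            nonsyn_multiplier=ds.nonsyn_multiplier))

    t0 = time.time()
    try:
        fits = fit_model_menu(blocks, n_starts=config.n_starts,
                              seed=config.seed, forms=config.forms,
                              shared_dfe=config.shared_dfe,
                              constrain_intercept=config.constrain_intercept,
                              p_neutral_free=config.p_neutral_free)
    except Exception as exc:  # noqa: BLE001
        fail("fit-models", exc)
    for form, r in fits.items():
        report["fits"][form] = {"params": r.params, "ll": r.ll,
                                "n_free_params": r.n_free_params,
                                "n_starts": r.n_starts, "seed": r.seed}
        log(f"fit[{form}]: LL={r.ll:.4f} params={r.params}")
    log(f"model fits done ({time.time() - t0:.1f}s)")

    order = [f for f in ("additive", "constant", "inverse", "logistic")
             if f in fits]
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            try:
                t = lrt(fits[order[a]], fits[order[b]])
            except ValueError:
                continue
            key = f"{order[a]}_vs_{order[b]}"
            report["lrt"][key] = {"lambda": t.lambda_, "df": t.df,
                                  "p_value": t.p_value}
            log(f"LRT {key}: Lambda={t.lambda_:.4f} df={t.df} "
                f"p={t.p_value:.3g}")
    if "inverse" in fits:
        rel = fits["inverse"].relationship()
        report["h_at_s"] = {str(s): float(rel.h_of_s(s))
                            for s in (-1e-4, -1e-3, -1e-2)}

    if config.bootstrap_B > 0:
        t0 = time.time()
        best_form = order[-1]
        spec = ModelSpec(best_form, blocks, shared_dfe=config.shared_dfe,
                         constrain_intercept=config.constrain_intercept,
                         p_neutral_free=config.p_neutral_free)
        try:
            bs = bootstrap(spec, B=config.bootstrap_B, seed=config.seed,
                           mle=fits[best_form])
        except Exception as exc:  # noqa: BLE001
            fail("bootstrap", exc)
        report["bootstrap"] = {
            "form": best_form, "B": config.bootstrap_B,
            "n_failures": bs["n_failures"],
            "params": {k: {"se": v["se"], "ci95": list(v["ci95"]),
                           "point": v["point"]}
                       for k, v in bs["params"].items()}}
        log(f"bootstrap[{best_form}]: B={config.bootstrap_B} "
            f"({time.time() - t0:.1f}s)")

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    _write_log(config, log_lines)
    return report


def _write_log(config: RunConfig, lines) -> None:
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
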
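"""Composite-likelihood inference of the DFE and dominance.

The data are folded synonymous and nonsynonymous spectra from an outcrossing
population and (optionally) a highly selfing one.  Inference proceeds
conditional on demographic models fitted to the synonymous spectra: the
nonsynonymous mutation rate is tied to the synonymous one
(theta_NS = 2.31 * theta_S), the model-expected nonsynonymous SFS comes from
integrating a cached (gamma, h) spectrum table against a gamma DFE with h
tied to s by the chosen dominance model, and entries are scored with the
Poisson random-field likelihood.  Log-likelihoods of the two populations add
(composite likelihood; allele frequencies across the species pair are treated
as independent).  The additive, constant-h and h-s relationship models are
nested, so likelihood-ratio tests with chi-square reference distributions
(df = difference in free parameters) compare them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .dfe import GammaDFE, HSRelationship, theta_nonsyn_from_syn
from .diffusion import DemographicModel, fit_demography
from .errors import OptimizationFailureError
from .grid import SFSGrid
from .sfs import SpectrumCounts, fold, poisson_resample

__all__ = [
    "DatasetBlock", "ModelSpec", "FitResult", "LRTResult",
    "poisson_ll", "composite_ll", "fit", "fit_model_menu", "lrt",
    "bootstrap", "z_compare",
]

LL_SENTINEL = -1e18

# optimizer bounds on the natural scale
BOUNDS = {
    "shape": (0.01, 5.0),
    "mean_s": (1e-6, 0.2),
    "theta_intercept": (1e-3, 1.0),
    "theta_rate": (0.0, 1e7),
    "h_const": (0.0, 1.0),
}
_RATE_UNIT = 1e4  # optimizer works on theta_rate / _RATE_UNIT


@dataclass
class DatasetBlock:
    """One population's data and its conditioning quantities."""

    name: str
    syn: SpectrumCounts
    nonsyn: SpectrumCounts
    demography: DemographicModel
    theta_syn: float
    F: float
    N_e: float
    grid: SFSGrid
    nonsyn_multiplier: float = 2.31

    @property
    def theta_nonsyn(self) -> float:
        return theta_nonsyn_from_syn(self.theta_syn, self.nonsyn_multiplier)


@dataclass
class ModelSpec:
    """A dominance/DFE model over one or two population datasets."""

    dominance_form: str  # additive | constant | inverse | logistic
    datasets: list
    shared_dfe: bool = True
    constrain_intercept: float | None = None
    p_neutral_free: bool = False

    def __post_init__(self):
        if self.dominance_form not in ("additive", "constant", "inverse",
                                       "logistic"):
            raise ValueError(f"unknown form {self.dominance_form!r}")
        if not self.datasets:
            raise ValueError("at least one dataset required")

    @property
    def n_dfe(self) -> int:
        return 1 if self.shared_dfe else len(self.datasets)

    @property
    def n_free_params(self) -> int:
        k = 2 * self.n_dfe
        if self.p_neutral_free:
            k += self.n_dfe
        k += HSRelationship._N_FREE[self.dominance_form]
        if self.constrain_intercept is not None and \
                self.dominance_form in ("inverse", "logistic"):
            k -= 1
        return k


@dataclass
class FitResult:
    """Maximum-likelihood parameters of one model fit."""

    params: dict
    ll: float
    form: str
    n_free_params: int
    start_lls: list = field(default_factory=list)
    n_starts: int = 0
    converged: bool = True
    seed: int | None = None

    def dfe(self, dataset_index: int = 0) -> GammaDFE:
        suffix = "" if "shape" in self.params else f"_{dataset_index}"
        shape = self.params[f"shape{suffix}"]
        mean_s = self.params[f"mean_s{suffix}"]
        return GammaDFE(shape, mean_s / shape,
                        self.params.get(f"p_neutral{suffix}", 0.0))

    def relationship(self) -> HSRelationship:
        p = self.params
        return HSRelationship(
            self.form,
            theta_intercept=p.get("theta_intercept", 0.5),
            theta_rate=p.get("theta_rate", 0.0),
            theta_offset=p.get("theta_offset", 0.0),
            h_const=p.get("h_const", 0.5),
            extend=True,
        )


@dataclass
class LRTResult:
    lambda_: float
    df: int
    p_value: float


def poisson_ll(observed: SpectrumCounts, expected: SpectrumCounts) -> float:
    """Poisson log-likelihood sum_i [X_i ln E_i - E_i - ln X_i!] over
    unmasked entries.  A zero expectation with a positive observation returns
    the large negative sentinel -1e18 so optimizers can recover."""
    if len(observed) != len(expected) or observed.folded != expected.folded:
        raise ValueError("observed and expected spectra are not aligned")
    um = ~(observed.mask | expected.mask)
    x = observed.counts[um]
    e = expected.counts[um]
    if np.any((e <= 0) & (x > 0)):
        return LL_SENTINEL
    pos = e > 0
    ll = float(np.sum(x[pos] * np.log(e[pos]) - e[pos]
                      - gammaln(x[pos] + 1.0)))
    return ll


# -- parameter packing ---------------------------------------------------


def _pack_names(spec: ModelSpec):
    names = []
    for d in range(spec.n_dfe):
        sfx = "" if spec.n_dfe == 1 else f"_{d}"
        names += [f"shape{sfx}", f"mean_s{sfx}"]
        if spec.p_neutral_free:
            names.append(f"p_neutral{sfx}")
    form = spec.dominance_form
    if form == "constant":
        names.append("h_const")
    elif form in ("inverse", "logistic"):
        if spec.constrain_intercept is None:
            names.append("theta_intercept")
        names.append("theta_rate")
        if form == "logistic":
            names.append("theta_offset")
    return names


def _to_internal(name: str, value: float) -> float:
    if name.startswith(("shape", "mean_s")):
        return np.log(value)
    if name.startswith("p_neutral") or name in ("theta_intercept", "h_const"):
        return logit(np.clip(value, 1e-6, 1 - 1e-6))
    if name == "theta_rate":
        return value / _RATE_UNIT
    return value  # theta_offset


def _from_internal(name: str, u: float) -> float:
    if name.startswith(("shape", "mean_s")):
        return float(np.exp(u))
    if name.startswith("p_neutral") or name in ("theta_intercept", "h_const"):
        return float(expit(u))
    if name == "theta_rate":
        return float(u * _RATE_UNIT)
    return float(u)


def _unpack(spec: ModelSpec, names, u) -> dict:
    params = {nm: _from_internal(nm, ui) for nm, ui in zip(names, u)}
    if spec.constrain_intercept is not None and \
            spec.dominance_form in ("inverse", "logistic"):
        params["theta_intercept"] = spec.constrain_intercept
    return params


def _within_bounds(params: dict) -> bool:
    for nm, v in params.items():
        base = nm.split("_0")[0].split("_1")[0] if nm[-2:] in ("_0", "_1") \
            else nm
        if base.startswith("shape"):
            lo, hi = BOUNDS["shape"]
        elif base.startswith("mean_s"):
            lo, hi = BOUNDS["mean_s"]
        elif base == "theta_rate":
            hi = BOUNDS["theta_rate"][1]
            lo = -hi  # two-sided internally; see fit() notes
        elif base in BOUNDS:
            lo, hi = BOUNDS[base]
        else:
            continue
        if not lo <= v <= hi:
            return False
    return True


def _rel_from_params(spec: ModelSpec, params: dict) -> HSRelationship:
    return HSRelationship(
        spec.dominance_form,
        theta_intercept=params.get("theta_intercept", 0.5),
        theta_rate=params.get("theta_rate", 0.0),
        theta_offset=params.get("theta_offset", 0.0),
        h_const=params.get("h_const", 0.5),
        extend=True,
    )


class _DatasetContext:
    """Precomputed raw arrays for fast repeated likelihood evaluation."""

    def __init__(self, ds: DatasetBlock):
        grid = ds.grid
        n = ds.nonsyn.sample_size
        # folding matrix: unfolded interior (n-1) -> folded (n//2)
        Ffold = np.zeros((n // 2, n - 1))
        for j in range(1, n // 2 + 1):
            Ffold[j - 1, j - 1] += 1.0
            if 2 * j != n:
                Ffold[j - 1, n - j - 1] += 1.0
        self.Ffold = Ffold
        self.gam = grid.gamma_axis
        self.svals = self.gam / ds.N_e
        dg = np.diff(self.gam)
        trap = np.zeros(len(self.gam))
        trap[:-1] += 0.5 * dg
        trap[1:] += 0.5 * dg
        self.trap = trap
        self.spectra = grid.spectra
        self.neutral = grid.neutral
        self.h_axis = grid.h_axis
        self.N_e = ds.N_e
        self.theta_nonsyn = ds.theta_nonsyn
        self.obs = ds.nonsyn.counts
        self.um = ~ds.nonsyn.mask
        self.lgam_obs = gammaln(self.obs[self.um] + 1.0)

    def expected_folded(self, shape, mean_s, p_neutral, rel) -> np.ndarray:
        from scipy.special import gammainc

        scale = mean_s / shape
        x = -self.svals  # |s| at the gamma nodes, positive
        # gamma pdf of |s| without scipy.stats dispatch overhead
        logpdf = (shape - 1.0) * np.log(x) - x / scale \
            - shape * np.log(scale) - gammaln(shape)
        pdf_gamma = np.exp(logpdf) / self.N_e
        w = self.trap * pdf_gamma * (1.0 - p_neutral)
        h = np.atleast_1d(rel.h_of_s(np.minimum(self.svals, 0.0)))
        idx = np.clip(np.searchsorted(self.h_axis, h), 1, len(self.h_axis) - 1)
        left, right = self.h_axis[idx - 1], self.h_axis[idx]
        h_idx = np.where(h - left <= right - h, idx - 1, idx)
        spectra = self.spectra[np.arange(len(self.gam)), h_idx, :]
        lethal = (1.0 - p_neutral) * (1.0 - gammainc(shape, -self.gam[0]
                                                     / (self.N_e * scale)))
        neutral = p_neutral + (1.0 - p_neutral) * gammainc(
            shape, -self.gam[-1] / (self.N_e * scale))
        e = w @ spectra + lethal * spectra[0] + neutral * self.neutral
        return self.theta_nonsyn * (self.Ffold @ np.maximum(e, 0.0))

    def poisson_ll_folded(self, expected: np.ndarray) -> float:
        x = self.obs[self.um]
        e = expected[self.um]
        if np.any((e <= 0) & (x > 0)):
            return LL_SENTINEL
        pos = e > 0
        return float(np.sum(x[pos] * np.log(e[pos]) - e[pos]
                            - self.lgam_obs[pos]))


_ctx_cache: dict = {}


def _context(ds: DatasetBlock) -> _DatasetContext:
    key = id(ds)
    ctx = _ctx_cache.get(key)
    if ctx is None or ctx._owner() is not ds:
        import weakref

        ctx = _DatasetContext(ds)
        ctx._owner = weakref.ref(ds)
        _ctx_cache[key] = ctx
    return ctx


def composite_ll(spec: ModelSpec, params: dict) -> float:
    """Composite log-likelihood: the sum over datasets of the Poisson
    log-likelihood of the folded nonsynonymous SFS under the model-expected
    spectrum (grid integration with h = f(s) for outcrossing data; the F = 1
    grid of a selfing dataset embeds the s_e = 2 s reduction and is
    h-independent)."""
    rel = _rel_from_params(spec, params)
    total = 0.0
    for d, ds in enumerate(spec.datasets):
        sfx = "" if spec.n_dfe == 1 else f"_{min(d, spec.n_dfe - 1)}"
        shape = params[f"shape{sfx}"]
        mean_s = params[f"mean_s{sfx}"]
        p_neutral = params.get(f"p_neutral{sfx}", 0.0)
        ctx = _context(ds)
        expected = ctx.expected_folded(shape, mean_s, p_neutral, rel)
        ll = ctx.poisson_ll_folded(expected)
        if ll <= LL_SENTINEL:
            return LL_SENTINEL
        total += ll
    return total


def _random_start(rng, names) -> dict:
    out = {}
    for nm in names:
        if nm.startswith("shape"):
            out[nm] = np.exp(rng.uniform(*np.log(BOUNDS["shape"])))
        elif nm.startswith("mean_s"):
            out[nm] = np.exp(rng.uniform(*np.log(BOUNDS["mean_s"])))
        elif nm.startswith("p_neutral"):
            out[nm] = rng.uniform(0.02, 0.5)
        elif nm == "theta_intercept":
            out[nm] = rng.uniform(0.1, 0.99)
        elif nm == "h_const":
            out[nm] = rng.uniform(0.05, 0.95)
        elif nm == "theta_rate":
            out[nm] = np.exp(rng.uniform(np.log(10.0), np.log(1e6)))
        elif nm == "theta_offset":
            out[nm] = rng.uniform(-2.0, 2.0)
    return out


def fit(spec: ModelSpec, n_starts: int = 50, seed: int = 0,
        warm_starts: list | None = None, maxfev: int = 500) -> FitResult:
    """Multi-start maximum-likelihood fit of a dominance/DFE model.

    Starting points are drawn uniformly (log-uniformly for scale-like
    parameters) within the bounds; ``warm_starts`` adds caller-supplied
    parameter dictionaries (e.g. the optimum of a nested null model, which
    also guarantees the fitted log-likelihoods respect model nesting).
    Optimization is Nelder-Mead on transformed coordinates.  The decay rate
    of the h-s relationship is searched on a two-sided interval (an estimated
    negative rate reads as "no decay detected"), which keeps the null
    hypothesis interior to the parameter space so that likelihood-ratio
    statistics follow their nominal chi-square asymptotics.
    """
    names = _pack_names(spec)
    rng = np.random.default_rng(seed)

    def neg(u):
        params = _unpack(spec, names, u)
        if not _within_bounds(params):
            return -LL_SENTINEL
        return -composite_ll(spec, params)

    starts = []
    for w in (warm_starts or []):
        filled = dict(_random_start(rng, names))
        filled.update({k: v for k, v in w.items() if k in names})
        starts.append(np.array([_to_internal(nm, filled[nm])
                                for nm in names]))
    for _ in range(n_starts):
        s = _random_start(rng, names)
        if "theta_rate" in s and rng.random() < 0.3:
            s["theta_rate"] = -s["theta_rate"]  # explore the two-sided axis
        starts.append(np.array([_to_internal(nm, s[nm]) for nm in names]))

    def _simplex(x0, step):
        sim = np.tile(x0, (len(x0) + 1, 1))
        for i in range(len(x0)):
            sim[i + 1, i] += step
        return sim

    best, start_lls = None, []
    for s0 in starts:
        r = minimize(neg, s0, method="Nelder-Mead",
                     options={"maxfev": maxfev, "xatol": 1e-5, "fatol": 1e-7,
                              "initial_simplex": _simplex(s0, 0.3)})
        start_lls.append(-r.fun)
        if np.isfinite(r.fun) and r.fun < -LL_SENTINEL / 2 and \
                (best is None or r.fun < best.fun):
            best = r
    if best is None:
        raise OptimizationFailureError("no fit start converged",
                                       incumbent=start_lls)
    # polish the incumbent twice, shrinking the simplex
    for step in (0.05, 0.01):
        r = minimize(neg, best.x, method="Nelder-Mead",
                     options={"maxfev": maxfev, "xatol": 1e-7, "fatol": 1e-10,
                              "initial_simplex": _simplex(best.x, step)})
        if r.fun < best.fun:
            best = r
    params = _unpack(spec, names, best.x)
    return FitResult(params=params, ll=-best.fun, form=spec.dominance_form,
                     n_free_params=spec.n_free_params, start_lls=start_lls,
                     n_starts=len(starts), converged=True, seed=seed)


def _adapt_warm(w: dict, form: str) -> dict:
    """Translate a fitted parameter dict into a warm start for ``form``."""
    w = dict(w)
    for k in ("theta_offset",):
        if form != "logistic":
            w.pop(k, None)
    if form == "additive":
        w.pop("h_const", None)
        w.pop("theta_intercept", None)
        w.pop("theta_rate", None)
    elif form == "constant":
        ti = w.pop("theta_intercept", None)
        w.pop("theta_rate", None)
        w.setdefault("h_const", ti if ti is not None else 0.5)
    elif form in ("inverse", "logistic"):
        hc = w.pop("h_const", None)
        w.setdefault("theta_intercept",
                     float(np.clip(hc if hc is not None else 0.5, 1e-3, 1.0)))
        w.setdefault("theta_rate", 0.0)
        if form == "logistic":
            w.setdefault("theta_offset", 0.0)
    return w


def fit_model_menu(datasets: list, n_starts: int = 20, seed: int = 0,
                   forms=("additive", "constant", "inverse"),
                   **spec_kwargs) -> dict:
    """Fit the nested dominance-model menu.

    An upward pass warm-starts each model from the nested optima below it; a
    downward pass then re-polishes each null model from the DFE parameters of
    the richer models above it.  Together these keep the fitted
    log-likelihoods monotone in model size and protect likelihood-ratio
    statistics from spurious inflation by an under-optimised null fit.
    """
    results = {}
    for i, form in enumerate(forms):
        spec = ModelSpec(form, datasets, **spec_kwargs)
        ws = [_adapt_warm(prev.params, form) for prev in results.values()]
        ws.append(_adapt_warm({"shape": 0.3, "mean_s": 5e-3}, form))
        results[form] = fit(spec, n_starts=n_starts, seed=seed + 7 * i,
                            warm_starts=ws)
    for i, form in enumerate(forms[:-1]):
        ws = [_adapt_warm(results[f].params, form)
              for f in forms[i + 1:]] + [results[form].params]
        spec = ModelSpec(form, datasets, **spec_kwargs)
        refit = fit(spec, n_starts=0, seed=seed + 100 + 7 * i,
                    warm_starts=ws)
        if refit.ll > results[form].ll:
            results[form] = refit
    return results


_NESTED_PAIRS = {
    ("additive", "constant"): 1,
    ("additive", "inverse"): 2,
    ("additive", "logistic"): 3,
    ("constant", "inverse"): 1,
    ("constant", "logistic"): 2,
}


def lrt(null: FitResult, alt: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested dominance models:
    Lambda = 2 (LL_alt - LL_null), chi-square with df = difference in free
    parameter count."""
    pair = (null.form, alt.form)
    if pair not in _NESTED_PAIRS:
        raise ValueError(f"models {pair} are not nested")
    lam = 2.0 * (alt.ll - null.ll)
    if lam < -1e-6:
        raise ValueError(
            f"alternative fit is worse than null by {lam / 2:.3g}; refit "
            "with warm starts")
    lam = max(lam, 0.0)
    df = _NESTED_PAIRS[pair]
    return LRTResult(lambda_=lam, df=df, p_value=float(stats.chi2.sf(lam, df)))


def bootstrap(spec: ModelSpec, B: int = 20, seed: int = 0,
              n_starts: int = 4, refit_demography: bool = False,
              mle: FitResult | None = None) -> dict:
    """Poisson-resampling bootstrap of all spectra with re-estimation.

    Each replicate Poisson-resamples the synonymous and nonsynonymous SFS of
    every dataset, re-estimates theta_syn (and, if ``refit_demography``, the
    size-change parameters) from the resampled synonymous SFS, and refits the
    selection model warm-started at the original MLE.  Returns per-parameter
    standard errors and normal-approximation 95% confidence intervals
    (mean +/- 1.96 SE).
    """
    mle = mle or fit(spec, n_starts=max(n_starts, 8), seed=seed)
    rng = np.random.default_rng(seed)
    estimates: list[dict] = []
    failures = 0
    for b in range(B):
        new_datasets = []
        ok = True
        for ds in spec.datasets:
            sub = int(rng.integers(0, 2**31 - 1))
            syn_b = poisson_resample(ds.syn, sub)
            ns_b = poisson_resample(ds.nonsyn, sub + 1)
            if refit_demography:
                try:
                    demog, th, _ = fit_demography(
                        syn_b, family=_family_name(ds.demography),
                        n_starts=4, seed=sub)
                except OptimizationFailureError:
                    ok = False
                    break
            else:
                demog = ds.demography
                from .diffusion import expected_sfs
                unit = fold(expected_sfs(demog, 0.0, 0.5, 0.0,
                                         syn_b.sample_size, 1.0,
                                         pts=200, extrap=False))
                um = ~syn_b.mask
                th = syn_b.counts[um].sum() / unit.counts[um].sum()
            new_datasets.append(replace(ds, syn=syn_b, nonsyn=ns_b,
                                        demography=demog, theta_syn=th))
        if not ok:
            failures += 1
            continue
        bspec = ModelSpec(spec.dominance_form, new_datasets,
                          shared_dfe=spec.shared_dfe,
                          constrain_intercept=spec.constrain_intercept,
                          p_neutral_free=spec.p_neutral_free)
        try:
            r = fit(bspec, n_starts=n_starts, seed=seed + 1000 + b,
                    warm_starts=[mle.params])
            estimates.append(r.params)
        except OptimizationFailureError:
            failures += 1
    out = {"estimates": estimates, "n_failures": failures,
           "flagged": failures > 0.2 * B, "params": {}}
    if estimates:
        for nm in estimates[0]:
            vals = np.array([e[nm] for e in estimates])
            se = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            m = float(np.mean(vals))
            out["params"][nm] = {
                "se": se, "ci95": (m - 1.96 * se, m + 1.96 * se),
                "mean": m, "point": mle.params.get(nm)}
    return out


def _family_name(demography: DemographicModel) -> str:
    return {0: "constant", 1: "two_epoch", 2: "three_epoch"}[
        len(demography.epochs)]


def z_compare(est_a: float, se_a: float, est_b: float, se_b: float,
              n_tests: int = 1):
    """Z-test of a parameter difference between two gene categories.

    The SE of the difference treats the category estimates as independent
    (disjoint gene sets): sqrt(se_a^2 + se_b^2).  Returns
    ``(Z, p_raw, p_bonferroni)`` with a two-sided normal p-value and
    Bonferroni correction over ``n_tests`` comparisons (capped at 1).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (est_a - est_b) / np.hypot(se_a, se_b)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p, min(1.0, p * n_tests)
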
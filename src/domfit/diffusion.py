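"""Poisson random field diffusion engine.

Expected site frequency spectra are computed from the 1-D forward (Kolmogorov)
diffusion of allele frequency x under selection, dominance, inbreeding and
piecewise-constant population size, with a steady influx of new mutations.
Per generation, with selection coefficient s, dominance h, inbreeding
coefficient F and population size N, the mean and variance of the change in
allele frequency p are

    M(p) = s p (1-p) { (1-F) [h + (1-2h) p] + F }
    V(p) = p (1-p) (1+F) / (2N)

For F = 0, h = 1/2 this is the additive outcrossing model; for F = 1 both
terms become independent of h and equal the additive model with selection
doubled and drift doubled, so a fully selfing population can be handled by an
additive engine with an effective selection coefficient s_e = 2 s at the
drift-matched effective size.

Time is measured in units of 2 N_anc generations and selection in the scaled
unit gamma = N_anc * s (N_anc the ancestral effective size).  The solver is a
Scharfetter-Gummel (exponentially fitted) finite-volume discretisation with
implicit time stepping; equilibrium epochs are solved directly as a linear
system.  Accuracy is optionally improved by Richardson extrapolation over two
frequency-grid resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import minimize
from scipy.special import gammaln

from .errors import NumericalFailureError, OptimizationFailureError
from .sfs import SpectrumCounts, fold

__all__ = [
    "DemographicModel",
    "PopulationContext",
    "drift_selection_terms",
    "expected_sfs",
    "selfing_effective_params",
    "fit_demography",
    "ancestral_ne",
]


@dataclass
class DemographicModel:
    """Piecewise-constant size history.

    ``epochs`` lists the post-ancestral epochs in time order as
    ``(relative_size, duration)`` pairs, sizes relative to the ancestral
    effective size and durations in units of 2 N_anc generations.  The
    ancestral epoch (relative size 1, unbounded duration) is implicit, so a
    constant-size model has no epochs, a two-epoch model one, a three-epoch
    model two.
    """

    epochs: tuple = ()

    def __post_init__(self):
        eps = []
        for nu, T in self.epochs:
            if nu <= 0:
                raise ValueError(f"relative size must be positive, got {nu}")
            if T <= 0:
                raise ValueError(f"epoch duration must be positive, got {T}")
            eps.append((float(nu), float(T)))
        self.epochs = tuple(eps)
        if len(self.epochs) > 2:
            raise ValueError("at most three epochs (two size changes) supported")

    @property
    def n_epochs(self) -> int:
        return 1 + len(self.epochs)

    def to_dict(self) -> dict:
        return {"epochs": [list(e) for e in self.epochs]}

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(tuple(tuple(e) for e in d.get("epochs", [])))


@dataclass
class PopulationContext:
    """Mutation-rate and mating-system context of one population."""

    N_anc: float
    F: float
    theta_syn: float
    mu: float = 7e-9
    L_syn: float = 0.0
    nonsyn_multiplier: float = 2.31

    def __post_init__(self):
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("inbreeding coefficient F must lie in [0, 1]")
        if self.theta_syn <= 0:
            raise ValueError("theta_syn must be positive")

    @property
    def theta_nonsyn(self) -> float:
        return self.theta_syn * self.nonsyn_multiplier


def drift_selection_terms(p, s: float, h: float, F: float, N: float):
    """Per-generation mean and variance of the allele-frequency change.

    Returns ``(M, V)`` evaluated elementwise at frequencies ``p`` in (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("allele frequency p must lie strictly in (0, 1)")
    G = (1.0 - F) * (h + (1.0 - 2.0 * h) * p) + F
    M = s * p * (1.0 - p) * G
    V = p * (1.0 - p) * (1.0 + F) / (2.0 * N)
    return M, V


def selfing_effective_params(s: float, h: float = 0.5):
    """Effective additive parameters for a fully selfing (F = 1) population.

    At F = 1 the diffusion is independent of h and identical to the additive
    outcrossing diffusion with twice the selection coefficient at the
    drift-matched effective size, so ``(s_e, h_e) = (2 s, 0.5)``.
    """
    return 2.0 * s, 0.5


def ancestral_ne(theta_syn: float, mu: float, L_syn: float) -> float:
    """Ancestral effective size from theta = 4 N_e mu L."""
    if mu <= 0 or L_syn <= 0:
        raise ValueError("mu and L_syn must be positive")
    if theta_syn <= 0:
        raise ValueError("theta_syn must be positive")
    return theta_syn / (4.0 * mu * L_syn)


# -- solver internals ----------------------------------------------------

_DEFAULT_PTS = 400
_CROWDING = 4.0


def _frequency_grid(npts: int, crwd: float = _CROWDING) -> np.ndarray:
    """Node positions on [0, 1] crowded toward the boundaries."""
    t = np.linspace(0.0, 1.0, npts + 2)
    x = 0.5 * (1.0 + np.tanh(crwd * (2.0 * t - 1.0)) / np.tanh(crwd))
    x[0], x[-1] = 0.0, 1.0
    return x


def _bernoulli(z: np.ndarray) -> np.ndarray:
    """B(z) = z / (exp(z) - 1), stable for large |z| and z ~ 0."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-8
    out[small] = 1.0 - 0.5 * z[small]
    zb = np.clip(z[~small], -700.0, 700.0)
    out[~small] = zb / np.expm1(zb)
    return out


def _operator_bands(x: np.ndarray, gamma: float, h: float, F: float,
                    nu: float):
    """Tridiagonal bands of the discrete drift-diffusion operator A.

    Interior unknowns phi_1..phi_J (density at nodes x_1..x_J); A phi gives
    d(phi)/dtau from flux differences of the Scharfetter-Gummel scheme applied
    to w = V phi with diffusion coefficient 1/2 and advection velocity
    M/V = 2 gamma nu G(x) / (1 + F).
    """
    J = len(x) - 2
    xi = x[1:-1]
    V = xi * (1.0 - xi) * (1.0 + F) / nu
    dx = np.diff(x)                       # length J+1, face spacings
    xf = 0.5 * (x[:-1] + x[1:])           # face positions
    G = (1.0 - F) * (h + (1.0 - 2.0 * h) * xf) + F
    a = 2.0 * gamma * nu * G / (1.0 + F)  # advection of w
    z = 2.0 * a * dx                      # a dx / D with D = 1/2
    D = 0.5
    Bm = _bernoulli(-z)                   # weight on left node
    Bp = _bernoulli(z)                    # weight on right node
    # flux through face f (between nodes f-1 and f, f = 1..J+1):
    #   G_f = (D/dx_f) [Bm_f w_{f-1} - Bp_f w_f]   with w_0 = w_{J+1} = 0
    cf = D / dx
    dc = 0.5 * (x[2:] - x[:-2])           # control volumes, length J
    # (A phi)_j = (G_{j} - G_{j+1}) / dc_j   (faces indexed by left node + 1)
    Vfull = np.concatenate([[0.0], V, [0.0]])
    lower = np.zeros(J)   # coefficient of phi_{j-1}
    diag = np.zeros(J)
    upper = np.zeros(J)   # coefficient of phi_{j+1}
    for j in range(1, J + 1):
        k = j - 1
        fl, fr = j - 1, j  # face indices into dx-arrays
        # incoming flux G_fl = cf[fl] (Bm[fl] w_{j-1} - Bp[fl] w_j)
        # outgoing flux G_fr = cf[fr] (Bm[fr] w_j   - Bp[fr] w_{j+1})
        diag[k] = (-cf[fl] * Bp[fl] - cf[fr] * Bm[fr]) * Vfull[j] / dc[k]
        if j > 1:
            lower[k] = cf[fl] * Bm[fl] * Vfull[j - 1] / dc[k]
        if j < J:
            upper[k] = cf[fr] * Bp[fr] * Vfull[j + 1] / dc[k]
    return lower, diag, upper, dc


def _source(x: np.ndarray, theta: float) -> np.ndarray:
    """Mutation-influx density rate: theta/2 of flux entering at the lowest
    interior node (mutations arise at frequency -> 0 at rate ~ theta/(2 x))."""
    J = len(x) - 2
    S = np.zeros(J)
    dc1 = 0.5 * (x[2] - x[0])
    S[0] = theta / (2.0 * x[1] * dc1)
    return S


def _solve_banded_tridiag(lower, diag, upper, rhs):
    J = len(diag)
    ab = np.zeros((3, J))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return solve_banded((1, 1), ab, rhs)


def _stationary_phi(x, gamma, h, F, nu, theta):
    lower, diag, upper, _ = _operator_bands(x, gamma, h, F, nu)
    S = _source(x, theta)
    phi = _solve_banded_tridiag(lower, diag, upper, -S)
    if not np.all(np.isfinite(phi)):
        raise NumericalFailureError(
            "stationary diffusion solve produced non-finite density",
            {"gamma": gamma, "h": h, "F": F, "nu": nu})
    return np.maximum(phi, 0.0)


def _integrate_epoch(phi, x, gamma, h, F, nu, T, theta, dt=1e-3):
    """Implicit-Euler integration of the density over one epoch."""
    lower, diag, upper, _ = _operator_bands(x, gamma, h, F, nu)
    S = _source(x, theta)
    nsteps = max(int(np.ceil(T / dt)), 20)
    step = T / nsteps
    J = len(diag)
    ab = np.zeros((3, J))
    ab[0, 1:] = -step * upper[:-1]
    ab[1, :] = 1.0 - step * diag
    ab[2, :-1] = -step * lower[1:]
    # factor once per epoch via LU inside solve_banded loop (cheap at this size)
    for _ in range(nsteps):
        phi = solve_banded((1, 1), ab, phi + step * S)
    if not np.all(np.isfinite(phi)):
        raise NumericalFailureError(
            "transient diffusion solve produced non-finite density",
            {"gamma": gamma, "h": h, "F": F, "nu": nu, "T": T})
    return np.maximum(phi, 0.0)


def _binomial_weights(n: int, x: np.ndarray) -> np.ndarray:
    """W[i-1, j] = C(n, i) x_j^i (1 - x_j)^(n-i) at interior nodes."""
    xi = x[1:-1]
    i = np.arange(1, n)[:, None]
    logc = (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1))
    with np.errstate(divide="ignore"):
        logw = logc + i * np.log(xi)[None, :] \
            + (n - i) * np.log1p(-xi)[None, :]
    return np.exp(logw)


def _sample_spectrum(phi, x, n):
    """E[X_i] = int phi(x) C(n,i) x^i (1-x)^(n-i) dx by trapezoid, with the
    boundary limits of the integrand filled in analytically."""
    W = _binomial_weights(n, x)
    integrand = np.zeros((n - 1, len(x)))
    integrand[:, 1:-1] = W * phi[None, :]
    # x -> 0: only i = 1 survives, limit n * (x phi)
    integrand[0, 0] = n * x[1] * phi[0]
    # x -> 1: only i = n-1 survives, limit n * ((1-x) phi)
    integrand[-1, -1] = n * (1.0 - x[-2]) * phi[-1]
    return np.trapezoid(integrand, x, axis=1)


def _expected_sfs_single(demography, gamma, h, F, n, theta, pts, dt):
    x = _frequency_grid(pts)
    phi = _stationary_phi(x, gamma, h, F, 1.0, theta)
    for nu, T in demography.epochs:
        phi = _integrate_epoch(phi, x, gamma, h, F, nu, T, theta, dt=dt)
    return _sample_spectrum(phi, x, n)


def expected_sfs(demography: DemographicModel, gamma: float, h: float,
                 F: float, n: int, theta: float, pts: int = _DEFAULT_PTS,
                 extrap: bool = True, dt: float = 1e-3) -> SpectrumCounts:
    """Expected unfolded SFS under the PRF model.

    Parameters
    ----------
    gamma:
        Scaled selection coefficient N_anc * s (<= 0; deleterious).
    h:
        Dominance coefficient in [0, 1].
    F:
        Inbreeding coefficient in [0, 1].  F = 1 is routed through the
        scaled-additive reduction (s_e = 2 s, h_e = 0.5).
    n:
        Sample size in allele copies.
    theta:
        Population mutation rate; expected counts are linear in theta.
    pts:
        Interior frequency-grid points (>= 400 by default).
    extrap:
        Richardson-extrapolate over grids of ``pts`` and ``2 pts`` interior
        points (second-order convergence in the grid spacing).
    """
    if gamma > 0:
        raise ValueError("only deleterious or neutral selection (gamma <= 0)")
    if not 0.0 <= h <= 1.0:
        raise ValueError("dominance h must lie in [0, 1]")
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if F >= 1.0:
        # fully selfing: h-independent, scaled-additive shortcut
        gamma, h, F = 2.0 * gamma, 0.5, 0.0
    e1 = _expected_sfs_single(demography, gamma, h, F, n, theta, pts, dt)
    if extrap:
        e2 = _expected_sfs_single(demography, gamma, h, F, n, theta,
                                  2 * pts, dt)
        e = (4.0 * e2 - e1) / 3.0
    else:
        e = e1
    e = np.maximum(e, 0.0)
    return SpectrumCounts(e, n, folded=False, label=f"gamma={gamma:g},h={h:g}")


# -- demographic fitting -------------------------------------------------

_FAMILIES = {"constant": 0, "two_epoch": 1, "three_epoch": 2}
_NU_BOUNDS = (1e-3, 1e3)
_T_BOUNDS = (1e-4, 5.0)


def _params_to_model(params: np.ndarray) -> DemographicModel:
    k = len(params) // 2
    eps = tuple((float(np.exp(params[2 * i])), float(np.exp(params[2 * i + 1])))
                for i in range(k))
    return DemographicModel(eps)


def _demog_ll(params, obs, n, pts, dt):
    """Profile Poisson log-likelihood: theta is scaled out analytically."""
    from .inference import poisson_ll
    k = len(params) // 2
    for i in range(k):
        nu, T = np.exp(params[2 * i]), np.exp(params[2 * i + 1])
        if not (_NU_BOUNDS[0] <= nu <= _NU_BOUNDS[1]
                and _T_BOUNDS[0] <= T <= _T_BOUNDS[1]):
            return -1e18, None, None
    model = _params_to_model(params)
    try:
        exp_unit = expected_sfs(model, 0.0, 0.5, 0.0, n, 1.0, pts=pts,
                                extrap=False, dt=dt)
    except NumericalFailureError:
        return -1e18, None, None
    exp_f = fold(exp_unit)
    um = ~obs.mask
    denom = exp_f.counts[um].sum()
    if denom <= 0:
        return -1e18, None, None
    theta_hat = obs.counts[um].sum() / denom
    expected = exp_f.copy()
    expected.counts = expected.counts * theta_hat
    ll = poisson_ll(obs, expected)
    return ll, theta_hat, model


def fit_demography(syn_spectrum: SpectrumCounts, family: str = "three_epoch",
                   n_starts: int = 10, seed: int = 0, pts: int = 200,
                   dt: float = 2e-3):
    """Maximum-Poisson-likelihood demographic fit to a folded synonymous SFS.

    The mutation-rate scale is profiled out analytically (the Poisson MLE of
    theta is total observed over total unit-theta expected); size-change
    parameters are found by multi-start BFGS in log coordinates followed by a
    Nelder-Mead polish.

    Returns ``(DemographicModel, theta_syn_hat, log_likelihood)``.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if not syn_spectrum.folded:
        syn_spectrum = fold(syn_spectrum)
    k = _FAMILIES[family]
    n = syn_spectrum.sample_size
    if k == 0:
        ll, theta_hat, model = _demog_ll(np.array([]), syn_spectrum, n,
                                         pts, dt)
        return model, theta_hat, ll

    rng = np.random.default_rng(seed)
    neg = lambda p: -_demog_ll(p, syn_spectrum, n, pts, dt)[0]
    best = None
    for _ in range(n_starts):
        start = np.empty(2 * k)
        start[0::2] = rng.uniform(np.log(0.05), np.log(20.0), k)   # log nu
        start[1::2] = rng.uniform(np.log(0.01), np.log(1.0), k)    # log T
        try:
            r = minimize(neg, start, method="BFGS",
                         options={"maxiter": 60, "gtol": 1e-6})
            r = minimize(neg, r.x, method="Nelder-Mead",
                         options={"maxiter": 400, "xatol": 1e-5,
                                  "fatol": 1e-7})
        except Exception:
            continue
        if np.isfinite(r.fun) and (best is None or r.fun < best.fun):
            best = r
    if best is None or best.fun >= 1e17:
        raise OptimizationFailureError(
            "no demographic optimization start converged", incumbent=best)
    ll, theta_hat, model = _demog_ll(best.x, syn_spectrum, n, pts, dt)
    return model, theta_hat, ll
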
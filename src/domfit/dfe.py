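"""Distribution of fitness effects and dominance-selection relationships.

The DFE of new nonsynonymous mutations is gamma-distributed over deleterious
selection coefficients (s <= 0 throughout; the gamma law describes |s|), with
an optional point mass of neutral mutations.  Dominance is tied to selection
through a parametric h-s relationship; the menu is

    additive    h = 0.5                                   (0 free parameters)
    constant    h = h_const                               (1)
    inverse     h = 1 / (1/theta_intercept - theta_rate*s)  (2)
    logistic    h = theta_intercept * (1 + exp(-theta_offset))
                    / (1 + exp(theta_rate*|s| - theta_offset))  (3)

theta_intercept is the dominance of an s = 0 mutation and theta_rate controls
how fast h decays toward zero as mutations become more deleterious; with
theta_rate -> 0 the inverse model collapses to constant h, and constant
h = 0.5 collapses to additive, so the three models are nested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidStateError
from .sfs import SpectrumCounts

__all__ = [
    "GammaDFE",
    "HSRelationship",
    "expected_nonsyn_sfs",
    "theta_nonsyn_from_syn",
    "discretize_gamma_dfe",
]


@dataclass
class GammaDFE:
    """Gamma distribution of |s| with an optional neutral point mass.

    ``scale`` is in units of the per-generation selection coefficient, so the
    mean deleterious effect is ``shape * scale``.
    """

    shape: float
    scale: float
    p_neutral: float = 0.0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if not 0.0 <= self.p_neutral <= 1.0:
            raise ValueError("p_neutral must lie in [0, 1]")

    @property
    def mean_s(self) -> float:
        """Mean |s| of the deleterious component."""
        return self.shape * self.scale

    def pdf_abs_s(self, x):
        """Density of |s| for the deleterious component (mass 1 - p_neutral)."""
        return (1.0 - self.p_neutral) * stats.gamma.pdf(x, self.shape,
                                                        scale=self.scale)

    def sample(self, rng, size):
        """Draw |s| magnitudes (0 for the neutral mass) from the DFE."""
        out = rng.gamma(self.shape, self.scale, size)
        if self.p_neutral > 0:
            out[rng.random(size) < self.p_neutral] = 0.0
        return out


@dataclass
class HSRelationship:
    """Parametric dominance function h = f(s) for s <= 0.

    ``extend=True`` permits a negative decay rate (h rising with |s|), with h
    clipped into [0, 1]; this keeps the null interior to the parameter space
    when the relationship is being estimated, and is only used internally by
    the fitting machinery.
    """

    form: str
    theta_intercept: float = 0.5
    theta_rate: float = 0.0
    theta_offset: float = 0.0
    h_const: float = 0.5
    extend: bool = False

    _N_FREE = {"additive": 0, "constant": 1, "inverse": 2, "logistic": 3}

    def __post_init__(self):
        if self.form not in self._N_FREE:
            raise ValueError(f"unknown dominance form {self.form!r}")
        if self.form in ("inverse", "logistic"):
            if not 0.0 < self.theta_intercept <= 1.0:
                raise ValueError("theta_intercept must lie in (0, 1]")
            if self.theta_rate < 0 and not self.extend:
                raise ValueError("theta_rate must be non-negative")
        if self.form == "constant" and not 0.0 <= self.h_const <= 1.0:
            raise ValueError("h_const must lie in [0, 1]")

    @property
    def n_free_params(self) -> int:
        return self._N_FREE[self.form]

    def h_of_s(self, s):
        """Dominance coefficient(s) for selection coefficient(s) s <= 0."""
        s = np.asarray(s, dtype=float)
        if np.any(s > 0):
            raise ValueError("h_of_s expects deleterious s <= 0")
        if self.form == "additive":
            h = np.full_like(s, 0.5)
        elif self.form == "constant":
            h = np.full_like(s, self.h_const)
        elif self.form == "inverse":
            denom = 1.0 / self.theta_intercept - self.theta_rate * s
            with np.errstate(divide="ignore"):
                h = np.where(denom > 1e-12, 1.0 / np.maximum(denom, 1e-12), 1.0)
        else:  # logistic
            z = self.theta_rate * np.abs(s) - self.theta_offset
            z = np.clip(z, -700.0, 700.0)
            h = self.theta_intercept * (1.0 + np.exp(-self.theta_offset)) \
                / (1.0 + np.exp(z))
        h = np.clip(h, 0.0, 1.0)
        return h if h.ndim else float(h)


def theta_nonsyn_from_syn(theta_syn: float, multiplier: float = 2.31) -> float:
    """Nonsynonymous mutation rate from the synonymous one, via the ratio of
    nonsynonymous to synonymous sequence length (default 2.31)."""
    if theta_syn <= 0:
        raise ValueError("theta_syn must be positive")
    return theta_syn * multiplier


def discretize_gamma_dfe(dfe: GammaDFE, N_e: float, n_bins: int):
    """Quantile-bin the deleterious DFE on the scaled-selection axis.

    Returns ``(gammas, masses)``: per-bin conditional mean gamma = -N_e |s|
    and the per-bin probability mass (the neutral point mass is excluded and
    handled by the caller).  Conditional means use the closed-form partial
    expectation of the gamma law.
    """
    q = np.linspace(0.0, 1.0, n_bins + 1)
    edges = stats.gamma.ppf(q, dfe.shape, scale=dfe.scale)
    edges[0], edges[-1] = 0.0, np.inf
    cdf_k = stats.gamma.cdf(edges, dfe.shape, scale=dfe.scale)
    cdf_k1 = stats.gamma.cdf(edges, dfe.shape + 1.0, scale=dfe.scale)
    mass = np.diff(cdf_k)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond_mean = dfe.shape * dfe.scale * np.diff(cdf_k1) / mass
    cond_mean = np.where(mass > 0, cond_mean, 0.0)
    gammas = -N_e * cond_mean
    w = (1.0 - dfe.p_neutral) * mass
    keep = w > 0
    return gammas[keep], w[keep]


def expected_nonsyn_sfs(grid, dfe: GammaDFE, rel: HSRelationship,
                        N_e: float, theta_nonsyn: float,
                        provenance: dict | None = None) -> SpectrumCounts:
    """Model-expected nonsynonymous SFS: the cached (gamma, h) spectra
    integrated against the DFE along gamma, with h tied to s by ``rel``.

    The integration is one-dimensional (each gamma maps to a single h): the
    grid's gamma nodes serve as trapezoid quadrature nodes for the gamma
    density; DFE mass beyond the lethal boundary (-N_e) is assigned to the
    boundary cell, and mass above the effectively-neutral cutoff plus any
    neutral point mass is assigned to the neutral spectrum.  The result
    scales linearly with ``theta_nonsyn``.
    """
    if provenance is not None:
        for key, val in provenance.items():
            if grid.provenance.get(key) != val:
                raise InvalidStateError(
                    f"grid provenance mismatch on {key!r}: "
                    f"{grid.provenance.get(key)} != {val}")
    gam = grid.gamma_axis  # ascending, negative
    svals = gam / N_e
    h_target = np.atleast_1d(rel.h_of_s(np.minimum(svals, 0.0)))
    h_idx = grid.nearest_h_index(h_target)
    spectra = grid.spectra[np.arange(len(gam)), h_idx, :]

    pdf_gamma = dfe.pdf_abs_s(-svals) / N_e  # density of gamma = -N_e |s|
    # trapezoid weights on the (non-uniform) gamma axis
    dg = np.diff(gam)
    w = np.zeros(len(gam))
    w[:-1] += 0.5 * dg
    w[1:] += 0.5 * dg
    w = w * pdf_gamma
    lethal_mass = (1.0 - dfe.p_neutral) * stats.gamma.sf(
        -gam[0] / N_e, dfe.shape, scale=dfe.scale)
    neutral_mass = dfe.p_neutral + (1.0 - dfe.p_neutral) * stats.gamma.cdf(
        -gam[-1] / N_e, dfe.shape, scale=dfe.scale)
    expected = w @ spectra
    expected = expected + lethal_mass * grid.spectra[0, h_idx[0], :]
    expected = expected + neutral_mass * grid.neutral
    expected = theta_nonsyn * expected
    n = grid.provenance["n"]
    return SpectrumCounts(np.maximum(expected, 0.0), n, folded=False,
                          label="expected nonsynonymous")
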
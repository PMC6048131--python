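"""Expression-cost model of dominance.

Fitness rises with gene expression level x with diminishing returns and falls
linearly with an expression cost c per unit:

    f(x) = (x + intercept * scale) (1 - c x) / (x + scale)

``intercept`` is the fitness of a gene expressed at zero (near 1 for a
non-essential gene, near 0 for an essential one) and ``scale`` is the
expression level at which, absent costs, fitness sits halfway between its
zero-expression and infinite-expression values (large for proteins needed in
many copies, small for catalytic proteins).  Regulatory sequence is assumed
optimally evolved, so genes sit at the expression optimum x_opt.  A
loss-of-function mutation halves functional protein when heterozygous
(x_opt / 2) and abolishes it when homozygous (x = 0), which pins down both
the selection and the dominance coefficient of the mutation:

    |s| = (f(x_opt) - f(0)) / f(x_opt)
    h   = (f(x_opt) - f(x_opt / 2)) / (f(x_opt) - f(0))

Selection coefficients are reported as s <= 0 (deleterious loss of function),
matching the convention of the inference modules; the magnitude is the ratio
above.  The model predicts recessivity (h < 0.5) that deepens with
deleteriousness, the pattern the SFS-based inference estimates from data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneExpressionModel", "simulate_ensemble", "ensemble_to_tsv",
           "plot_hs_prediction"]


@dataclass
class GeneExpressionModel:
    """One gene's (c, intercept, scale) triple."""

    c: float
    intercept: float
    scale: float

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("expression cost c must be non-negative")
        if not 0.0 <= self.intercept <= 1.0:
            raise ValueError("intercept must lie in [0, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.c > 0 and self.intercept < 1.0:
            # reject genes whose optimum would sit past the point where the
            # linear cost drives fitness negative
            xo = self._x_opt_raw()
            if xo is not None and self.c * xo >= 1.0:
                raise ValueError("cost term exceeds 1 within the evaluated "
                                 "expression range")

    def fitness(self, x):
        """f(x) for expression level x >= 0."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("expression level must be non-negative")
        f = (x + self.intercept * self.scale) * (1.0 - self.c * x) \
            / (x + self.scale)
        return f if f.ndim else float(f)

    def _x_opt_raw(self):
        if self.intercept >= 1.0:
            return None
        if self.c == 0.0:
            return None  # fitness increases monotonically, no finite optimum
        rad = self.scale * self.c * (1.0 - self.intercept) \
            * (1.0 + self.scale * self.c)
        return float(np.sqrt(rad) / self.c - self.scale)

    def optimal_expression(self) -> float:
        """Positive root of df/dx = 0:
        x_opt = sqrt(scale c (1-intercept)(1 + scale c)) / c - scale.
        Raises if no positive optimum exists (intercept >= 1: removing the
        gene is costless, fitness is maximal at x = 0)."""
        xo = self._x_opt_raw()
        if xo is None or xo <= 0:
            raise ValueError("no positive expression optimum for these "
                             "parameters (intercept too close to 1)")
        return xo

    def s_and_h(self, expression_fraction: float = 1.0):
        """Selection and dominance coefficients of a loss-of-function
        mutation, optionally at suboptimal expression (e.g. 0.8 of x_opt).

        Returns ``(s, h)`` with s <= 0.
        """
        if not 0.0 < expression_fraction <= 1.0:
            raise ValueError("expression_fraction must lie in (0, 1]")
        x_star = expression_fraction * self.optimal_expression()
        f_full = self.fitness(x_star)
        f_half = self.fitness(x_star / 2.0)
        f_zero = self.fitness(0.0)
        s = -(f_full - f_zero) / f_full
        denom = f_full - f_zero
        h = (f_full - f_half) / denom if denom != 0 else 0.5
        return float(s), float(h)


def simulate_ensemble(n_genes: int = 5000, c: float = 0.001,
                      intercept_low: float = 0.9, intercept_high: float = 1.0,
                      scale_mean: float = 0.1, scale_sd: float = 0.1,
                      expression_fraction: float = 1.0,
                      seed: int = 0) -> pd.DataFrame:
    """Gene-ensemble simulation of the dominance model.

    Intercepts are uniform on [intercept_low, intercept_high) (most new
    mutations nearly neutral), scales are |Normal(scale_mean, scale_sd)|
    (optimal expression skewed toward low values), and the cost c is shared.
    Genes without a positive expression optimum (intercept at 1, or the
    optimum formally non-positive) are recorded with s = 0 and h = NaN and
    are excluded from dominance statistics.

    Returns a DataFrame with columns gene, c, intercept, scale, x_opt, s, h.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        intercept = rng.uniform(intercept_low, intercept_high)
        scale = abs(rng.normal(scale_mean, scale_sd))
        scale = max(scale, 1e-9)
        try:
            model = GeneExpressionModel(c, intercept, scale)
            x_opt = model.optimal_expression()
            s, h = model.s_and_h(expression_fraction)
        except ValueError:
            rows.append((g, c, intercept, scale, np.nan, 0.0, np.nan))
            continue
        rows.append((g, c, intercept, scale, x_opt, s, h))
    return pd.DataFrame(rows, columns=["gene", "c", "intercept", "scale",
                                       "x_opt", "s", "h"])


def ensemble_to_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def plot_hs_prediction(df: pd.DataFrame, ax=None):
    """Scatter the predicted (|s|, h) cloud of a simulated gene ensemble."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    kept = df.dropna(subset=["h"])
    ax.scatter(-kept["s"], kept["h"], s=4, alpha=0.3)
    ax.set_xscale("log")
    ax.set_xlabel("|s| of loss of function")
    ax.set_ylabel("dominance h")
    ax.set_ylim(0, 0.55)
    return ax
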
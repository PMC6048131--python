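"""Cached 2-D lookup tables of expected SFS over (N_e s, h).

Computing the expected SFS for every (scaled selection, dominance) pair a DFE
integration needs is expensive, but the SFS varies smoothly across close
(gamma, h) values.  A coarse grid (default 50 x 20) is therefore computed by
the diffusion engine — exponential spacing in gamma from -N_e (lethal) to
-1e-4 (effectively neutral), linear in h on [0, 1] — and refined to a much
finer lattice (default 1000 x 1000) by a two-pass cubic-spline interpolation
of each frequency entry: first along the gamma axis holding h fixed, then
along the h axis.  Scaled selection below |gamma| = 1e-4 is served by the
demography-matched neutral spectrum rather than the solver.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.interpolate import CubicSpline

from .diffusion import DemographicModel, expected_sfs
from .errors import InvalidStateError, NumericalFailureError
from .sfs import SpectrumCounts

__all__ = ["SFSGrid", "build_coarse", "refine", "lookup", "save_grid",
           "load_grid", "load_or_build"]

NEUTRAL_CUTOFF = 1e-4


@dataclass
class SFSGrid:
    """Expected unit-theta SFS on a (gamma, h) lattice.

    ``spectra[i, j, :]`` is the expected unfolded SFS at ``gamma_axis[i]``
    (ascending, negative) and ``h_axis[j]``; ``neutral`` is the expected SFS
    at gamma = 0 under the same demography.  ``provenance`` records the
    demography, sample size, inbreeding coefficient and N_e the grid is valid
    for; lookups key on it to avoid silent stale caches.
    """

    gamma_axis: np.ndarray
    h_axis: np.ndarray
    spectra: np.ndarray
    neutral: np.ndarray
    provenance: dict
    resolution: str = "coarse"
    invalid: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_clamped: int = 0

    def __post_init__(self):
        self.gamma_axis = np.asarray(self.gamma_axis, dtype=float)
        self.h_axis = np.asarray(self.h_axis, dtype=float)
        if np.any(np.diff(self.gamma_axis) <= 0) or \
                np.any(np.diff(self.h_axis) < 0):
            raise ValueError("grid axes must be monotone")
        if self.invalid is None:
            self.invalid = np.zeros(
                (len(self.gamma_axis), len(self.h_axis)), dtype=bool)

    # gamma spacing is uniform in log|gamma|; nearest-node distances use the
    # native coordinate of each axis
    def nearest_gamma_index(self, gamma) -> np.ndarray:
        logg = np.log(np.clip(-np.asarray(gamma, dtype=float),
                              -self.gamma_axis[-1], -self.gamma_axis[0]))
        axis = np.log(-self.gamma_axis[::-1])
        idx = np.clip(np.searchsorted(axis, logg), 1, len(axis) - 1)
        left = axis[idx - 1]
        right = axis[idx]
        nearer = np.where(logg - left <= right - logg, idx - 1, idx)
        return (len(axis) - 1) - nearer  # undo the reversal

    def nearest_h_index(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        idx = np.clip(np.searchsorted(self.h_axis, h), 1, len(self.h_axis) - 1)
        left = self.h_axis[idx - 1]
        right = self.h_axis[idx]
        return np.where(h - left <= right - h, idx - 1, idx)

    def cache_key(self) -> str:
        payload = json.dumps(
            {"provenance": _jsonable(self.provenance),
             "gamma": [float(self.gamma_axis[0]), float(self.gamma_axis[-1]),
                       len(self.gamma_axis)],
             "h": [float(self.h_axis[0]), float(self.h_axis[-1]),
                   len(self.h_axis)]},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _jsonable(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = [list(e) if isinstance(e, tuple) else e for e in v]
        out[k] = v
    return out


def gamma_axis_exponential(N_e: float, points: int) -> np.ndarray:
    """Ascending gamma nodes from -N_e (lethal) to -1e-4 (effectively
    neutral), uniform in log|gamma|."""
    return -np.exp(np.linspace(np.log(N_e), np.log(NEUTRAL_CUTOFF), points))


def build_coarse(demography: DemographicModel, n: int, N_e: float,
                 F: float = 0.0, gamma_points: int = 50, h_points: int = 20,
                 pts: int = 400, extrap: bool = True) -> SFSGrid:
    """Compute the coarse grid of expected unit-theta spectra.

    Solver failures at individual cells are tolerated: the cell is flagged
    invalid and the build continues (the failure count is recorded in the
    provenance).  For F = 1 the expected SFS is independent of h, so a single
    column is computed and broadcast.
    """
    gammas = gamma_axis_exponential(N_e, gamma_points)
    hs = np.linspace(0.0, 1.0, h_points)
    spectra = np.zeros((gamma_points, h_points, n - 1))
    invalid = np.zeros((gamma_points, h_points), dtype=bool)
    h_iter = [0.5] if F >= 1.0 else hs
    n_failures = 0
    for i, g in enumerate(gammas):
        for j, h in enumerate(h_iter):
            try:
                e = expected_sfs(demography, g, h, F, n, 1.0, pts=pts,
                                 extrap=extrap)
                if F >= 1.0:
                    spectra[i, :, :] = e.counts[None, :]
                else:
                    spectra[i, j, :] = e.counts
            except NumericalFailureError:
                n_failures += 1
                if F >= 1.0:
                    invalid[i, :] = True
                else:
                    invalid[i, j] = True
    neutral = expected_sfs(demography, 0.0, 0.5, min(F, 1.0), n, 1.0,
                           pts=pts, extrap=extrap).counts
    prov = {"demography": demography.epochs, "n": n, "F": float(F),
            "N_e": float(N_e), "n_failures": n_failures}
    return SFSGrid(gammas, hs, spectra, neutral, prov, resolution="coarse",
                   invalid=invalid)


def refine(grid: SFSGrid, gamma_points: int = 1000,
           h_points: int = 1000) -> SFSGrid:
    """Two-pass per-frequency cubic-spline refinement of a coarse grid.

    Pass one interpolates each frequency entry along the gamma axis (in its
    native log|gamma| coordinate) holding h fixed; pass two interpolates the
    result along the h axis.  The fine axes include the coarse nodes, so
    values there are preserved exactly.  Spline undershoot below zero is
    clamped to 0 and counted.
    """
    if grid.resolution != "coarse":
        raise InvalidStateError("refine expects a coarse grid")
    cg = np.log(-grid.gamma_axis)          # descending in log|gamma|
    fine_lg = np.union1d(
        np.linspace(cg[-1], cg[0], gamma_points), cg)
    fine_gamma = -np.exp(fine_lg[::-1])    # ascending gamma
    fine_lg_sorted = fine_lg               # ascending log|gamma|
    fine_h = np.union1d(np.linspace(grid.h_axis[0], grid.h_axis[-1],
                                    h_points), grid.h_axis)
    G, H = len(fine_gamma), len(fine_h)
    nfreq = grid.spectra.shape[2]

    valid_rows = ~grid.invalid.any(axis=1)
    cg_sorted = cg[::-1]                    # ascending log|gamma|
    # interpolate log spectra: entries fall off exponentially with gamma * h
    # toward the lethal-recessive corner, where a linear-space spline cannot
    # track the decay; the log transform keeps the two-pass scheme accurate
    # there and positive everywhere
    _FLOOR = 1e-280
    sp_sorted = np.log(np.maximum(grid.spectra[::-1, :, :], _FLOOR))
    use = valid_rows[::-1]
    mid = np.empty((G, len(grid.h_axis), nfreq))
    for j in range(len(grid.h_axis)):
        for f in range(nfreq):
            cs = CubicSpline(cg_sorted[use], sp_sorted[use, j, f])
            mid[:, j, f] = cs(fine_lg_sorted)
    fine = np.empty((G, H, nfreq))
    for i in range(G):
        for f in range(nfreq):
            cs = CubicSpline(grid.h_axis, mid[i, :, f])
            fine[i, :, f] = cs(fine_h)
    fine = np.exp(fine[::-1, :, :])         # back to ascending gamma order
    fine[fine <= 2 * _FLOOR] = 0.0
    n_clamped = int(np.sum(fine < 0))
    fine = np.maximum(fine, 0.0)
    fine_invalid = np.zeros((G, H), dtype=bool)
    if not valid_rows.all():
        bad_idx = grid.nearest_gamma_index(fine_gamma)
        fine_invalid[:, :] = (~valid_rows)[bad_idx][:, None]
    return SFSGrid(fine_gamma, fine_h, fine, grid.neutral.copy(),
                   dict(grid.provenance), resolution="fine",
                   invalid=fine_invalid, n_clamped=n_clamped)


def lookup(grid: SFSGrid, gamma: float, h: float) -> SpectrumCounts:
    """Nearest-node spectrum at (gamma, h), unit theta.

    gamma in (-1e-4, 0] maps to the neutral spectrum; gamma below -N_e clamps
    to the lethal boundary.
    """
    if grid.spectra.size == 0:
        raise InvalidStateError("empty grid")
    n = grid.provenance["n"]
    if gamma > 0:
        raise ValueError("lookup expects gamma <= 0")
    if gamma > -NEUTRAL_CUTOFF:
        return SpectrumCounts(grid.neutral.copy(), n, folded=False,
                              label="neutral")
    gi = int(grid.nearest_gamma_index(gamma))
    hj = int(grid.nearest_h_index(h))
    return SpectrumCounts(grid.spectra[gi, hj, :].copy(), n, folded=False,
                          label=f"grid({grid.gamma_axis[gi]:g},{grid.h_axis[hj]:g})")


def save_grid(grid: SFSGrid, path) -> None:
    """Persist a grid to an HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("gamma_axis", data=grid.gamma_axis)
        fh.create_dataset("h_axis", data=grid.h_axis)
        fh.create_dataset("spectra", data=grid.spectra)
        fh.create_dataset("neutral", data=grid.neutral)
        fh.create_dataset("invalid", data=grid.invalid)
        fh.attrs["provenance"] = json.dumps(_jsonable(grid.provenance),
                                            sort_keys=True)
        fh.attrs["resolution"] = grid.resolution
        fh.attrs["n_clamped"] = grid.n_clamped
        fh.attrs["cache_key"] = grid.cache_key()


def load_grid(path) -> SFSGrid:
    with h5py.File(path, "r") as fh:
        prov = json.loads(fh.attrs["provenance"])
        prov["demography"] = tuple(tuple(e) for e in prov["demography"])
        return SFSGrid(
            fh["gamma_axis"][:], fh["h_axis"][:], fh["spectra"][:],
            fh["neutral"][:], prov, resolution=str(fh.attrs["resolution"]),
            invalid=fh["invalid"][:], n_clamped=int(fh.attrs["n_clamped"]))


def load_or_build(path, demography: DemographicModel, n: int, N_e: float,
                  F: float = 0.0, gamma_points: int = 50, h_points: int = 20,
                  refine_to: tuple | None = None, **build_kwargs) -> SFSGrid:
    """Load a cached grid if its provenance matches; rebuild otherwise.

    ``refine_to=(G, H)`` additionally spline-refines a freshly built grid.
    """
    import os

    want = {"demography": demography.epochs, "n": n, "F": float(F),
            "N_e": float(N_e)}
    if os.path.exists(path):
        try:
            grid = load_grid(path)
            if all(grid.provenance.get(k) == v for k, v in want.items()):
                return grid
        except Exception:
            pass
    grid = build_coarse(demography, n, N_e, F, gamma_points, h_points,
                        **build_kwargs)
    if refine_to is not None:
        grid = refine(grid, *refine_to)
    save_grid(grid, path)
    return grid
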
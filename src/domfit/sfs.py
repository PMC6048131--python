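"""Site frequency spectrum containers and transformations.

A site frequency spectrum (SFS) summarises polymorphism data as the number of
segregating sites observed at each sample allele count.  Unfolded spectra count
derived-allele copies (1..n-1 of n sampled copies); folded spectra count
minor-allele copies (1..floor(n/2)), the form used when no ancestral state can
be assigned.  Expected spectra (real-valued) and observed spectra (integer
counts) share the same container.

The on-disk format is a dadi-style whitespace text dialect:

    <n+1> {folded|unfolded} [label]
    <counts ...>
    <mask ...>

An unfolded file carries n+1 count values (entries 0 and n are the monomorphic
classes, conventionally masked); a folded file carries floor(n/2)+1 values
(entry 0 masked).  Mask values of 1 flag entries excluded from likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import InvalidStateError, SpectrumParseError

__all__ = [
    "SpectrumCounts",
    "neutral_spectrum",
    "fold",
    "project",
    "poisson_resample",
    "read_spectrum",
    "write_spectrum",
    "spectrum_from_counts",
    "read_minor_allele_table",
]


def _interior_length(n: int, folded: bool) -> int:
    return n // 2 if folded else n - 1


@dataclass
class SpectrumCounts:
    """Counts of segregating sites per sample allele count.

    Parameters
    ----------
    counts:
        Entry ``i`` (0-based) holds the number of sites at allele count
        ``i + 1``.  Length ``n - 1`` if unfolded, ``floor(n / 2)`` if folded.
    sample_size:
        Number of sampled allele copies ``n`` (>= 2).
    folded:
        Whether counts are indexed by minor-allele count.
    label:
        Free-text tag (species, mutation class).
    mask:
        Boolean array aligned with ``counts``; ``True`` marks entries excluded
        from likelihood computations.  Defaults to all-unmasked.
    """

    counts: np.ndarray
    sample_size: int
    folded: bool = False
    label: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n = int(self.sample_size)
        if n < 2:
            raise ValueError(f"sample_size must be >= 2, got {n}")
        self.sample_size = n
        expected = _interior_length(n, self.folded)
        if self.counts.ndim != 1 or len(self.counts) != expected:
            raise ValueError(
                f"counts has length {len(self.counts)}, expected {expected} for "
                f"n={n} {'folded' if self.folded else 'unfolded'}"
            )
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")
        if self.mask is None:
            self.mask = np.zeros(expected, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if len(self.mask) != expected:
                raise ValueError("mask length must match counts length")

    # -- convenience ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.sample_size

    def copy(self) -> "SpectrumCounts":
        return SpectrumCounts(
            self.counts.copy(), self.sample_size, self.folded, self.label,
            self.mask.copy(),
        )

    def total(self) -> float:
        """Total count over unmasked entries."""
        return float(self.counts[~self.mask].sum())

    def allele_counts(self) -> np.ndarray:
        """The sample allele counts the entries correspond to (1-based)."""
        return np.arange(1, len(self.counts) + 1)

    def __len__(self) -> int:
        return len(self.counts)


def neutral_spectrum(n: int, theta: float = 1.0, folded: bool = False,
                     label: str = "neutral") -> SpectrumCounts:
    """Equilibrium neutral spectrum E[X_i] = theta / i (folded on request)."""
    i = np.arange(1, n)
    unfolded = SpectrumCounts(theta / i, n, folded=False, label=label)
    return fold(unfolded) if folded else unfolded


def fold(spectrum: SpectrumCounts) -> SpectrumCounts:
    """Fold an unfolded spectrum onto minor-allele counts.

    Entry j of the folded spectrum combines derived-allele counts j and n-j;
    for even n the central class n/2 is its own minor-allele class and is
    counted once.  The total count is conserved.
    """
    if spectrum.folded:
        raise InvalidStateError("spectrum is already folded")
    n = spectrum.sample_size
    k = n // 2
    out = np.zeros(k)
    out_mask = np.zeros(k, dtype=bool)
    c = spectrum.counts
    m = spectrum.mask
    for j in range(1, k + 1):
        if 2 * j == n:
            out[j - 1] = c[j - 1]
            out_mask[j - 1] = m[j - 1]
        else:
            out[j - 1] = c[j - 1] + c[n - j - 1]
            out_mask[j - 1] = m[j - 1] or m[n - j - 1]
    return SpectrumCounts(out, n, folded=True, label=spectrum.label,
                          mask=out_mask)


def _project_unfolded(counts: np.ndarray, n: int, m: int) -> np.ndarray:
    """Hypergeometric projection of unfolded interior counts from n to m copies."""
    # weight[i, j] = P(j of m | i of n) = C(i,j) C(n-i, m-j) / C(n, m)
    i = np.arange(1, n)[:, None]
    j = np.arange(1, m)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = (
            _log_comb(i, j) + _log_comb(n - i, m - j) - _log_comb(n, m)
        )
    w = np.where(np.isfinite(logw), np.exp(logw), 0.0)
    return counts @ w


def _log_comb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    bad = (b < 0) | (b > a)
    with np.errstate(invalid="ignore"):
        out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where(bad, -np.inf, out)


def project(spectrum: SpectrumCounts, m: int) -> SpectrumCounts:
    """Project a spectrum down to a smaller sample size m by hypergeometric
    downsampling.  Classes that become monomorphic (0 or m copies) are dropped,
    so the expected total count never increases.  Folded input is projected by
    splitting each minor-allele class symmetrically over its two unfolded
    pre-images, projecting, and refolding.
    """
    n = spectrum.sample_size
    if not 2 <= m <= n:
        raise ValueError(f"projection size m={m} must satisfy 2 <= m <= n={n}")
    if m == n:
        return spectrum.copy()
    if spectrum.folded:
        unf = np.zeros(n - 1)
        k = n // 2
        for j in range(1, k + 1):
            if 2 * j == n:
                unf[j - 1] = spectrum.counts[j - 1]
            else:
                unf[j - 1] = spectrum.counts[j - 1] / 2.0
                unf[n - j - 1] = spectrum.counts[j - 1] / 2.0
        projected = _project_unfolded(unf, n, m)
        out = SpectrumCounts(projected, m, folded=False, label=spectrum.label)
        return fold(out)
    projected = _project_unfolded(spectrum.counts, n, m)
    return SpectrumCounts(projected, m, folded=False, label=spectrum.label)


def poisson_resample(spectrum: SpectrumCounts, seed: int) -> SpectrumCounts:
    """Draw each entry independently from Poisson(mean = input entry).

    This is the parametric bootstrap step for Poisson-random-field data:
    entry counts are independent Poissons, so resampling the spectrum is
    equivalent to resampling sites.
    """
    rng = np.random.default_rng(seed)
    out = rng.poisson(spectrum.counts).astype(float)
    return SpectrumCounts(out, spectrum.sample_size, spectrum.folded,
                          spectrum.label, spectrum.mask.copy())


def read_minor_allele_table(path, n: int,
                            column: str = "minor_allele_count"
                            ) -> SpectrumCounts:
    """Build a folded SFS from a per-site TSV table.

    The table needs a ``minor_allele_count`` column (configurable); other
    columns (site identifiers, annotations) are ignored.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    if column not in table.columns:
        raise SpectrumParseError(
            f"column {column!r} not found in {path} "
            f"(columns: {list(table.columns)})")
    return spectrum_from_counts(table[column].astype(int).tolist(), n)


def spectrum_from_counts(minor_allele_counts, n: int) -> SpectrumCounts:
    """Histogram per-site minor-allele counts (1..floor(n/2)) into a folded SFS."""
    k = n // 2
    counts = np.zeros(k)
    for c in minor_allele_counts:
        c = int(c)
        if not 1 <= c <= k:
            raise ValueError(
                f"minor allele count {c} outside 1..{k} for n={n}"
            )
        counts[c - 1] += 1
    return SpectrumCounts(counts, n, folded=True)


# -- file I/O ------------------------------------------------------------


def write_spectrum(spectrum: SpectrumCounts, path) -> None:
    """Write a spectrum in the dadi-style .fs text dialect (12 significant
    digits, so write->read round-trips to printed precision)."""
    n = spectrum.sample_size
    if spectrum.folded:
        vals = np.concatenate([[0.0], spectrum.counts])
        mask = np.concatenate([[True], spectrum.mask])
    else:
        vals = np.concatenate([[0.0], spectrum.counts, [0.0]])
        mask = np.concatenate([[True], spectrum.mask, [True]])
    lines = [
        f"{n + 1} {'folded' if spectrum.folded else 'unfolded'}"
        + (f" \"{spectrum.label}\"" if spectrum.label else ""),
        " ".join(f"{v:.12g}" for v in vals),
        " ".join("1" if m else "0" for m in mask),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spectrum(path) -> SpectrumCounts:
    """Read a spectrum written by :func:`write_spectrum`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise SpectrumParseError("expected header, counts and mask lines",
                                 line=len(lines) + 1)
    head = lines[0].split()
    if len(head) < 2:
        raise SpectrumParseError("header must be '<n+1> {folded|unfolded}'",
                                 line=1)
    try:
        n = int(head[0]) - 1
    except ValueError:
        raise SpectrumParseError(f"bad sample-size field {head[0]!r}", line=1)
    if head[1] not in ("folded", "unfolded"):
        raise SpectrumParseError(f"bad folding flag {head[1]!r}", line=1)
    folded = head[1] == "folded"
    label = ""
    if len(head) > 2:
        label = " ".join(head[2:]).strip('"')
    try:
        vals = np.array([float(v) for v in lines[1].split()])
    except ValueError:
        raise SpectrumParseError("counts line contains non-numeric value",
                                 line=2)
    expect = (n // 2 + 1) if folded else (n + 1)
    if len(vals) != expect:
        raise SpectrumParseError(
            f"counts line has {len(vals)} values, expected {expect} for "
            f"n={n} {'folded' if folded else 'unfolded'}", line=2)
    maskvals = lines[2].split()
    if len(maskvals) != expect:
        raise SpectrumParseError(
            f"mask line has {len(maskvals)} values, expected {expect}", line=3)
    mask = np.array([v == "1" for v in maskvals])
    if folded:
        counts, m = vals[1:], mask[1:]
    else:
        counts, m = vals[1:-1], mask[1:-1]
    return SpectrumCounts(counts, n, folded=folded, label=label, mask=m)
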
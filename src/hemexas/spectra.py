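"""Spectrum containers and two-column text I/O.

Scans and chi(k) spectra travel as plain two-column whitespace text with
``#``-prefixed header lines carrying metadata (XDI-style), the lingua
franca of XAS beamlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


def _check_grid(x, name):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"{name} must be a 1-d array with >= 2 points")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    if not np.all(np.diff(x) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return x


@dataclass
class RawScan:
    """One energy-indexed absorption scan (measured or simulated)."""

    energy: np.ndarray
    mu: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energy = _check_grid(self.energy, "energy")
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != self.energy.shape:
            raise ValueError("energy and mu must have the same length")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mu contains non-finite values")

    def copy(self):
        return RawScan(self.energy.copy(), self.mu.copy(), dict(self.meta))


@dataclass
class AveragedSpectrum:
    """Pointwise mean of repeat scans with a scalar noise estimate.

    ``noise`` is the statistical noise of the averaged spectrum in units
    of the edge step (filled by ``preprocess.estimate_noise``).
    """

    energy: np.ndarray
    mu_mean: np.ndarray
    noise: float = np.nan
    n_scans: int = 1
    noise_approximate: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class NormalizedSpectrum:
    """Edge-step normalized absorption with its background model."""

    energy: np.ndarray
    mu_norm: np.ndarray
    e0: float
    edge_step: float
    background: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class ChiSpectrum:
    """EXAFS oscillation chi(k) on a photoelectron-wavevector grid."""

    k: np.ndarray
    chi: np.ndarray
    kweight: int = 1
    noise_k: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=float)
        if np.any(self.k < 0) or not np.all(np.diff(self.k) > 0):
            raise ValueError("k must be non-negative and strictly increasing")
        self.chi = np.asarray(self.chi, dtype=float)
        if self.chi.shape != self.k.shape:
            raise ValueError("k and chi must have the same length")
        if not np.all(np.isfinite(self.chi)):
            raise ValueError("chi contains non-finite values")

    @property
    def weighted(self):
        """k^w * chi(k)."""
        return self.k**self.kweight * self.chi

    def crop(self, k_min, k_max):
        sel = (self.k >= k_min - 1e-12) & (self.k <= k_max + 1e-12)
        if sel.sum() < 2:
            raise ValueError(
                f"k-range [{k_min}, {k_max}] outside data "
                f"[{self.k[0]:.2f}, {self.k[-1]:.2f}]"
            )
        return replace(self, k=self.k[sel], chi=self.chi[sel])


@dataclass
class FTSpectrum:
    """Fourier transform of windowed k-weighted chi(k) into R-space."""

    r: np.ndarray
    ft_complex: np.ndarray
    window: tuple
    kweight: int

    @property
    def modulus(self):
        return np.abs(self.ft_complex)


# ---------------------------------------------------------------------------
# text I/O


def write_columns(path, columns, names, meta=None):
    """Write named columns as whitespace text with ``#`` headers."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# " + "  ".join(names) + "\n")
        np.savetxt(fh, np.column_stack(columns), fmt="%.8g")


def read_columns(path):
    """Read whitespace-column text; returns (array, meta dict)."""
    meta = {}
    with open(path) as fh:
        text = fh.readlines()
    for line in text:
        if line.startswith("#") and ":" in line:
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    data = np.loadtxt([ln for ln in text if not ln.startswith("#")])
    return np.atleast_2d(data), meta


def write_scan(path, scan):
    write_columns(path, (scan.energy, scan.mu), ("energy_eV", "mu"), scan.meta)


def read_scan(path):
    data, meta = read_columns(path)
    return RawScan(data[:, 0], data[:, 1], meta)


def write_chi(path, chi):
    meta = dict(chi.meta)
    meta["kweight"] = chi.kweight
    write_columns(path, (chi.k, chi.chi), ("k_invA", "chi"), meta)


def read_chi(path):
    data, meta = read_columns(path)
    kweight = int(meta.pop("kweight", 1))
    return ChiSpectrum(data[:, 0], data[:, 1], kweight=kweight, meta=meta)
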
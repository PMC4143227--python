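"""Forward-model generator for synthetic Fe K-edge absorption data.

Builds complete raw scans - linear pre-edge, arctangent edge step, slow
post-edge background, EXAFS oscillations from a shell model, optional
pre-edge Gaussian features and Gaussian measurement noise - with the
statistical structure of averaged fluorescence-detected protein XAS
(repeat-scan series, noise at the 1e-3 level of the edge step).  Every
downstream stage of the package is testable against these spectra because
the embedded truth is recorded in the scan metadata.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_E0, DEFAULT_NOISE_SD, K_CONV
from .forward import simulate_chi
from .spectra import ChiSpectrum, RawScan

__all__ = [
    "simulate_chi",
    "default_edge",
    "embed_mu",
    "simulate_scan",
    "make_scan_series",
    "simulate_preedge",
    "PREEDGE_PRESETS",
]


def default_edge():
    """Default edge-embedding parameters (all configurable).

    ``e0``: arctangent center, eV; ``step``: edge-step height (absorption
    units); ``width``: arctangent half-width, eV; ``pre_slope`` /
    ``pre_intercept``: linear pre-edge absorption; ``post_curve``:
    coefficients (c1, c2) of the slow post-edge polynomial in
    x = (E - e0)/1000.
    """
    return {
        "e0": DEFAULT_E0,
        "step": 1.0,
        "width": 1.5,
        "pre_slope": -2.0e-5,
        "pre_intercept": 0.35,
        "post_curve": (-0.08, 0.03),
    }


def _edge_shape(energy, e0, width):
    return 0.5 + np.arctan((energy - e0) / width) / np.pi


def embed_mu(chi, edge=None, energy=None, energy_step=0.5, pre_span=150.0):
    """Embed a chi(k) spectrum into a full raw absorption scan.

    mu(E) = line(E) + step * S(E) * [1 + P(E) + chi(k(E)) * T(k)]

    with S the arctangent edge shape, P the slow post-edge polynomial and
    T a low-k taper (chi is physically meaningless at the edge itself).
    The inverse of the reduction chain: running the scan through
    ``preprocess`` recovers chi to a few 1e-3.
    """
    edge = {**default_edge(), **(edge or {})}
    e0, step, width = edge["e0"], edge["step"], edge["width"]
    if energy is None:
        e_max = e0 + chi.k[-1] ** 2 / K_CONV
        energy = np.arange(e0 - pre_span, e_max + 0.5 * energy_step, energy_step)
    energy = np.asarray(energy, dtype=float)
    if energy[-1] <= e0:
        raise ValueError("energy grid must extend above the edge")

    line = edge["pre_intercept"] + edge["pre_slope"] * (energy - e0)
    shape = _edge_shape(energy, e0, width)
    x = np.clip(energy - e0, 0.0, None) / 1000.0
    c1, c2 = edge["post_curve"]
    post = c1 * x + c2 * x * x

    k_of_e = np.sqrt(np.clip(K_CONV * (energy - e0), 0.0, None))
    chi_e = np.interp(k_of_e, chi.k, chi.chi, left=0.0, right=0.0)
    # cosine taper switching the oscillation on over k in [1, 2] A^-1
    taper = np.clip((k_of_e - 1.0) / 1.0, 0.0, 1.0)
    taper = np.sin(0.5 * np.pi * taper) ** 2

    mu = line + step * shape * (1.0 + post + chi_e * taper)
    meta = {
        "synthetic": True,
        "truth_e0": e0,
        "truth_step": step,
        "truth_chi_kmin": float(chi.k[0]),
        "truth_chi_kmax": float(chi.k[-1]),
    }
    return RawScan(energy, mu, meta)


def simulate_scan(model, funcs, k_grid=None, edge=None, **embed_kw):
    """Shell model -> full raw scan (simulate_chi + embed_mu)."""
    if k_grid is None:
        k_grid = np.arange(0.5, 12.0, 0.02)
    chi = simulate_chi(model, funcs, k_grid)
    scan = embed_mu(chi, edge=edge, **embed_kw)
    scan.meta["truth_model"] = model
    return scan


def make_scan_series(scan, n, noise_sd=DEFAULT_NOISE_SD, seed=0):
    """n independent noisy copies of a scan (zero-mean Gaussian noise).

    ``noise_sd`` is in absorption units (for edge-step-normalized
    synthetic scans this equals edge-step units).  Bitwise reproducible
    from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    series = []
    for i in range(n):
        noisy = scan.copy()
        if noise_sd > 0:
            noisy.mu = noisy.mu + rng.normal(0.0, noise_sd, size=noisy.mu.shape)
        noisy.meta.update(scan_index=i, noise_sd=noise_sd, seed=seed)
        series.append(noisy)
    return series


#: Truth parameters of the packaged pre-edge segments, in normalized
#: absorption units.  The hexa-coordinated (drug-bound-like) preset has a
#: second peak exactly 2 eV above the main one.
PREEDGE_PRESETS = {
    "penta_like": {
        "arctan": (0.30, 7120.0, 3.0),
        "gaussians": [(7113.0, 0.08, 0.8)],
    },
    "hexa_like": {
        "arctan": (0.30, 7120.0, 3.0),
        "gaussians": [(7112.8, 0.05, 0.7), (7114.8, 0.03, 0.7)],
    },
}


def simulate_preedge(
    preset="penta_like",
    params=None,
    energy=None,
    noise_sd=0.0,
    seed=0,
):
    """Synthetic pre-edge segment: arctangent continuum + Gaussian peaks.

    ``preset`` is ``penta_like`` (one localized-state peak) or
    ``hexa_like`` (main peak A plus peak B 2 eV above); ``params``
    overrides entries of the preset dict.  Truth parameters are recorded
    in the scan metadata.
    """
    if preset not in PREEDGE_PRESETS:
        raise KeyError(
            f"unknown pre-edge preset {preset!r}; valid: "
            f"{sorted(PREEDGE_PRESETS)}"
        )
    p = {**PREEDGE_PRESETS[preset], **(params or {})}
    if energy is None:
        energy = np.arange(7102.0, 7117.0 + 0.025, 0.05)
    energy = np.asarray(energy, dtype=float)
    amp, center, width = p["arctan"]
    mu = amp * (0.5 + np.arctan((energy - center) / width) / np.pi)
    for c, h, sig in p["gaussians"]:
        mu = mu + h * np.exp(-0.5 * ((energy - c) / sig) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mu = mu + rng.normal(0.0, noise_sd, size=mu.shape)
    meta = {"synthetic": True, "preset": preset, "truth": p, "noise_sd": noise_sd}
    return RawScan(energy, mu, meta)
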
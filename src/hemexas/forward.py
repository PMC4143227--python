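"""The single-scattering EXAFS forward model.

chi(k) is a sum of Gaussian-disorder shell contributions

    chi(k) = S0^2 * sum_j  N_j / (k r_j^2) * |f_j(k)|
             * exp(-2 sigma2_j k^2) * exp(-2 r_j / lambda_j(k))
             * sin(2 k r_j + phi_j(k))

evaluated at the shifted wavevector k' = sqrt(k^2 - K_CONV * dE) when the
edge-energy shift dE is nonzero (the data's k-grid is defined against a
nominal E0; dE re-references it).  This one implementation serves both the
synthetic-spectrum generator and the fitting engine, so fits of
self-generated data are exact by construction.
"""

from __future__ import annotations

import numpy as np

from .constants import K_CONV
from .spectra import ChiSpectrum


def _effective_k(k, delta_e):
    """Re-reference the wavevector grid for an edge-energy shift dE (eV)."""
    if delta_e == 0.0:
        return np.asarray(k, dtype=float)
    k2 = np.asarray(k, dtype=float) ** 2 - K_CONV * delta_e
    return np.sqrt(np.clip(k2, 1e-6, None))


def resolve_sigma2(model):
    """Per-shell sigma2 with ``sigma2_tied_to`` links resolved."""
    out = {}
    for shell in model.shells:
        if shell.sigma2_tied_to is not None:
            out[shell.label] = model[shell.sigma2_tied_to].sigma2
        else:
            out[shell.label] = shell.sigma2
    return out


def shell_chi(shell, sigma2, s02, funcs, k):
    """Contribution of one shell on an (already dE-shifted) k grid."""
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("k must be strictly positive")
    amp = funcs.amplitude(k)
    lam = funcs.mean_free_path(k)
    phase = funcs.phase(k)
    return (
        s02
        * shell.N
        / (k * shell.r**2)
        * amp
        * np.exp(-2.0 * sigma2 * k * k)
        * np.exp(-2.0 * shell.r / lam)
        * np.sin(2.0 * k * shell.r + phase)
    )


def simulate_chi(model, funcs, k_grid, kweight=1, return_partials=False):
    """Evaluate the shell sum on ``k_grid``.

    Parameters
    ----------
    model : ShellModel
    funcs : dict
        element symbol -> :class:`ScatteringFunctions`.
    k_grid : array
        Strictly increasing, k > 0, in A^-1 (nominal grid; the model's
        dE re-maps it internally).
    return_partials : bool
        Also return an ordered dict label -> per-shell ChiSpectrum.

    Returns
    -------
    ChiSpectrum (and optionally the partials dict).
    """
    k_grid = np.asarray(k_grid, dtype=float)
    if np.any(k_grid <= 0) or not np.all(np.diff(k_grid) > 0):
        raise ValueError("k_grid must be strictly increasing and > 0")
    k_eff = _effective_k(k_grid, model.delta_e)
    sigma2 = resolve_sigma2(model)
    total = np.zeros_like(k_grid)
    partials = {}
    for shell in model.shells:
        if shell.element not in funcs:
            raise KeyError(
                f"shell {shell.label!r}: no scattering functions for "
                f"element {shell.element!r}"
            )
        contrib = shell_chi(
            shell, sigma2[shell.label], model.s02, funcs[shell.element], k_eff
        )
        total = total + contrib
        if return_partials:
            partials[shell.label] = ChiSpectrum(
                k_grid, contrib, kweight=kweight, meta={"shell": shell.label}
            )
    out = ChiSpectrum(k_grid, total, kweight=kweight, meta={"model": "forward"})
    if return_partials:
        return out, partials
    return out
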
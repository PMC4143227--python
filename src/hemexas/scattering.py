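"""Backscattering amplitude, phase-shift and mean-free-path functions.

EXAFS modelling needs, for every backscatterer species j, the photoelectron
backscattering amplitude ``|f_j(k)|``, the total phase shift ``phi_j(k)``
(absorber plus backscatterer) and the inelastic mean free path
``lambda(k)``.  Production analyses compute these ab initio (FEFF); this
package ships smooth analytic parameterizations for the light scatterers
relevant to a heme site (N, O, C):

    |f(k)|   = a * exp(-b k) / (1 + c k^2)        (dimensionless)
    phi(k)   = p0 + p1 * k                        (rad; p1 in rad*A)
    lambda(k)= l0 + l1 * k                        (A)

A linear phase with slope p1 shifts the apparent distance of a shell in the
Fourier transform by p1/2; the packaged slope of -1.0 rad*A for N, O and C
reproduces the ~0.5 A compression of FT peak positions familiar from light
scatterers at the Fe K edge.  Tabulated (k, |f|, phi, lambda) columns - e.g.
from a FEFF run - can be loaded with :meth:`ScatteringFunctions.from_table`
and used everywhere the analytic forms are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline


@dataclass(frozen=True)
class ScatteringFunctions:
    """Scattering functions for one backscatterer element.

    Parameters
    ----------
    element : str
        Chemical symbol of the backscatterer.
    amplitude_params : tuple
        ``(a, b, c)`` of the analytic amplitude envelope.
    phase_params : tuple
        ``(p0, p1)`` or ``(p0, p1, p2)`` of the phase polynomial in k.
    lambda_params : tuple
        ``(l0, l1)`` of the linear mean free path, in A.
    """

    element: str
    amplitude_params: tuple = (1.0, 0.1, 0.02)
    phase_params: tuple = (0.0, -1.0)
    lambda_params: tuple = (5.0, 0.5)
    _tables: dict = field(default=None, repr=False, compare=False)

    def amplitude(self, k):
        """|f(k)|, dimensionless, for k in A^-1."""
        k = np.asarray(k, dtype=float)
        if self._tables is not None:
            return np.clip(self._tables["amp"](k), 1e-12, None)
        a, b, c = self.amplitude_params
        return a * np.exp(-b * k) / (1.0 + c * k * k)

    def phase(self, k):
        """Total phase shift phi(k) in radians."""
        k = np.asarray(k, dtype=float)
        if self._tables is not None:
            return self._tables["phase"](k)
        return np.polynomial.polynomial.polyval(k, self.phase_params)

    def mean_free_path(self, k):
        """Inelastic mean free path lambda(k) in A (floored at 3 A)."""
        k = np.asarray(k, dtype=float)
        if self._tables is not None:
            lam = self._tables["mfp"](k)
        else:
            l0, l1 = self.lambda_params
            lam = l0 + l1 * k
        return np.clip(lam, 3.0, None)

    @property
    def phase_slope(self):
        """Linear phase slope p1 in rad*A, or None for non-linear phase.

        Tabulated functions get an effective slope from a least-squares
        line through phi(k) on k in [3, 11]; analytic phases with a
        curvature term report None.
        """
        if self._tables is not None:
            k = np.linspace(3.0, 11.0, 81)
            return float(np.polyfit(k, self.phase(k), 1)[0])
        if len(self.phase_params) > 2 and self.phase_params[2] != 0.0:
            return None
        return float(self.phase_params[1])

    @classmethod
    def from_table(cls, element, k, amp, phase, mfp):
        """Build from tabulated columns (k, |f|, phi, lambda).

        Cubic-spline interpolation in k; extrapolation holds the spline's
        polynomial tail, so supply tables covering the working k-range.
        """
        k = np.asarray(k, dtype=float)
        tables = {
            "amp": InterpolatedUnivariateSpline(k, np.asarray(amp, float), k=3),
            "phase": InterpolatedUnivariateSpline(k, np.asarray(phase, float), k=3),
            "mfp": InterpolatedUnivariateSpline(k, np.asarray(mfp, float), k=3),
        }
        return cls(element=element, _tables=tables)


# Packaged analytic coefficients for the heme-site scatterers.  Amplitudes
# follow the usual light-atom ordering O > N > C and decay with k; the
# common -1.0 rad*A phase slope fixes the FT peak compression at 0.5 A.
_DEFAULTS = {
    "N": ScatteringFunctions("N", (0.95, 0.12, 0.015), (1.8, -1.0), (4.0, 0.6)),
    "O": ScatteringFunctions("O", (1.05, 0.13, 0.015), (2.0, -1.0), (4.0, 0.6)),
    "C": ScatteringFunctions("C", (0.85, 0.11, 0.016), (1.6, -1.0), (4.0, 0.6)),
}


def default_scattering(element):
    """Packaged analytic scattering functions for element N, O or C.

    Raises
    ------
    KeyError
        For elements without a packaged parameterization.
    """
    try:
        return _DEFAULTS[element]
    except KeyError:
        raise KeyError(
            f"no packaged scattering functions for element {element!r}; "
            f"available: {sorted(_DEFAULTS)}"
        ) from None


def default_scattering_map(elements=("N", "O", "C")):
    """Dict of element -> ScatteringFunctions for the given elements."""
    return {el: default_scattering(el) for el in elements}
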
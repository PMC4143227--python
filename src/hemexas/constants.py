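"""Physical constants and package-wide defaults."""

#: hbar^2 / 2 m_e conversion between photoelectron kinetic energy and
#: wavevector squared: k^2 [A^-2] = K_CONV * (E - E0 - dE) [eV].
K_CONV = 0.2624682

#: Tabulated Fe K-edge ionization energy, eV.
FE_K_EDGE = 7112.0

#: Edge position used by the synthetic spectrum generator, eV.  The edge of
#: the embedded arctangent step sits slightly above the tabulated atomic
#: value, as it does for ferric iron in a protein matrix.
DEFAULT_E0 = 7122.0

#: Default uniform k-grid for chi(k) work, A^-1.
DEFAULT_K_MIN = 2.5
DEFAULT_K_MAX = 11.0
DEFAULT_K_STEP = 0.05

#: Default k-weight exponent w in k^w * chi(k).
DEFAULT_KWEIGHT = 1

#: Statistical noise of a well-averaged fluorescence spectrum, in units of
#: the edge step (the generator's default).
DEFAULT_NOISE_SD = 1.0e-3
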
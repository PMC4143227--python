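# Methods

This note documents the models, conventions and defaults behind
`hemexas`, and what the synthetic test bed does and does not establish.

## The physical problem

Fe K-edge (7.112 keV) absorption of a dilute metalloprotein, measured in
fluorescence with a multi-element detector. The extended oscillatory part
of the spectrum, χ(k), encodes the distances r, multiplicities N and
Gaussian disorder σ² (mean square relative displacement) of the
coordination shells around the absorber; the near-edge pre-edge peak
indexes the coordination number through the dipole-forbidden 1s→3d
channel. For heme-albumin the structural question is whether the ferric
iron is five-coordinate (4 porphyrin N ~2.07 Å + Tyr phenoxy O ~2.5 Å)
or gains a sixth nitrogen neighbor at ~2.15 Å upon allosteric drug
binding.

## Forward model

Single-scattering Gaussian shell sum:

χ(k) = S₀² Σⱼ Nⱼ/(k rⱼ²) |fⱼ(k)| exp(−2σⱼ²k²) exp(−2rⱼ/λ(k)) sin(2krⱼ + φⱼ(k))

An edge-energy shift ΔE re-references the wavevector grid,
k′ = √(k² − 0.2624682·ΔE). One implementation serves the generator and
the fitter, so fits of self-generated data close exactly; this is a
deliberate test-bed property, not evidence about real data (see
*Limitations*).

**Scattering functions.** Production analyses take |f|, φ and λ from ab
initio codes. This package ships analytic stand-ins for N, O and C:
|f(k)| = a·e^(−bk)/(1+ck²), φ(k) = p₀ + p₁k, λ(k) = l₀ + l₁k (floored at
3 Å). The shared slope p₁ = −1.0 rad·Å fixes the Fourier-peak
compression of light scatterers at 0.5 Å, the familiar magnitude at the
Fe K edge; amplitudes follow the light-atom ordering O > N > C.
Tabulated (k, |f|, φ, λ) columns can be loaded with
`ScatteringFunctions.from_table` and drop in everywhere. Because the
analytic N/O/C functions differ only mildly, synthetic fits can trade
amplitude between nitrogen and oxygen shells more cheaply than real
scattering allows — relevant to the bound-pinning behavior below.

## Reduction chain

- **E0**: first maximum of the 5-point-smoothed derivative, parabolic
  sub-grid refinement, ties toward lower energy. Flat or
  boundary-maximum derivatives raise (no edge in range).
- **Pre-edge line**: least squares over [E_min, E0−30 eV], subtracted
  everywhere.
- **Edge step**: post-edge trend step·(1 + c₁x + c₂x² + c₃/x) over
  x = E−E0 ∈ [20, 400] eV, extrapolated to E0. The 1/x term absorbs the
  slow resonance tail of the edge; without it the extrapolation biases
  the step (hence all χ amplitudes) several percent low.
- **Background**: the same trend plus a cubic least-squares spline on
  its residual, fitted in k-space with interior knots every 3.0 Å⁻¹
  (≈ the conventional ~1 Å background cutoff, spacing ≈ π/R_bkg).
  Spacings below 1.5 Å⁻¹ are refused: the first-shell oscillation period
  is π/r ≈ 1.5 Å⁻¹ and a denser spline starts absorbing signal. With
  the defaults, embedding a known χ and re-extracting it returns it with
  RMS error ~7×10⁻⁴ on k ∈ [3, 11] Å⁻¹, and the extracted oscillation
  retains >95% of its power.
- **k grid**: uniform, step 0.05 Å⁻¹, default window 2.5–11 Å⁻¹;
  k-weight w = 1 throughout. The underlying study does not fix its
  k-range or weight; these are package defaults, fully configurable.
- **Noise**: per-energy standard error of the mean over repeat scans,
  averaged over a 200 eV post-edge window, divided by the edge step.
  A single scan falls back to the Savitzky–Golay smoothing residual
  (flagged approximate).
- **Radiation-damage QC**: per-scan E0 minus the first scan's E0;
  offsets beyond 0.3 eV (default) flag photo-reduction suspects.

## Refinement

The fit minimizes A(θ) = Σ[k^w(χ_obs − χ_model)]² under parameter bounds
(scipy trust-region-reflective least squares), from the nominal start
plus two seeded, 2%-jittered restarts (deterministic given the seed).
Default bounds: N ∈ [0.05, 20], r ∈ [1, 6] Å, σ² ∈ [0, 0.1] Å²,
S₀² ∈ [0.1, 1.2], ΔE ∈ [−15, 15] eV; per-shell overrides via
`Shell.bounds`. A shell's σ² may be tied to another shell's (used for
the weak sixth-neighbor shell, whose disorder is not independently
determined).

Metrics: with σ_w the statistical noise mapped to weighted units
(σ_χ·√⟨k^2w⟩), χ²ν = A/(σ_w²(n−p)) and R² = A/Σ(k^w χ_obs)². When no
noise estimate is supplied, σ_w is scaled from the best-fit residual
(χ²ν then pins at 1 and is labelled as such in `summary()`). On
correctly specified synthetic data with injected noise, χ²ν calibrates
to 1 and the ±1σ intervals cover truth at the expected rate (verified
in the test suite over 20 seeded replicates).

**Uncertainties.** Covariance σ from the Jacobian at the optimum;
asymmetric intervals from MINOS-style profile scans: the parameter is
stepped outward (initial step 0.05σ, geometric growth), all other free
parameters re-minimized at each point, and the Δχ² = 1 crossing of the
unreduced χ² refined by root bracketing. Bound hits are returned as the
distance to the bound and flagged; unbracketed crossings are flagged
open.

**Model comparison.** The richer model is preferred only if it lowers
R² by ≥20% (configurable), by a non-negligible absolute margin, and
without any of its parameters pinning at bounds — an extra shell must
pay for itself. The verdict text also notes when the *simpler* model
pins parameters, the signature of underfitting.

## Fourier analysis

FT(R) = (1/√π) Σ k^w χ(k) W(k) e^{2ikR} dk on r ∈ [0, 6] Å (dr = 0.02),
W a Hann-tapered rectangle (default window 2.5–11 Å⁻¹, tapers 0.5 Å⁻¹).
The e^{2ikR} kernel makes a pure sin(2kr₀) peak at r₀ exactly; the
convention is stated here because different packages differ and peak
positions move with it. Peaks are read off the modulus with parabolic
refinement; `phase_corrected_distance` adds back −p₁/2 (= +0.5 Å for
the packaged functions). Parseval's identity (Σ|FT|²dr = ½Σ|k^wχW|²dk)
holds to <1% and is asserted in the tests.

## Pre-edge

Segment default [E0−20, E0−5] eV. Model: arctangent continuum onset
plus 1 or 2 Gaussians parameterized by (center, height, σ); "width"
means the Gaussian σ, not FWHM, and the integrated area is h·σ·√(2π) —
stated because area conventions vary. The area-weighted mean center is
the centroid. The lmfit-backed bounded fit is deterministic given its
initial values.

Classification places (centroid, area) in rectangular reference
regions. **The packaged region table is a placeholder**: the literature
reference-compound boundaries are not reproduced here, and the shipped
rectangles are positioned to contain the package's own synthetic
presets while following the physical trend (lower coordination → larger
area). It is an editable text file; substitute measured regions before
classifying real data.

## Crystallographic shells

PDB structures are parsed with gemmi (first model, highest-occupancy
altloc, hydrogens excluded from neighbor work). Default distance
windows (Å): N [1.8, 2.3], O [2.3, 3.0], C [2.9, 3.25], C [3.25, 3.7],
C [4.0, 4.5] — resolving the porphyrin first shell, axial O, the two
inner carbon rings and the outer ring. Near-collinear Fe–A–B paths are
searched with A in the first shell (≤2.5 Å) and B within 2.6 Å of A;
the 2.6 Å cutoff deliberately covers the 1–3 N···C_β contact (~2.25 Å)
of the porphyrin, whose ~170° Fe–N–C_β alignment produces the strong
multiple-scattering that excludes the outer carbon ring from
single-scattering fits. `synthetic_heme_site()` provides an idealized,
geometrically constructed heme pocket (not deposited coordinates) used
by the test suite; the extraction machinery runs unchanged on real PDB
files.

## Synthetic generator

`embed_mu` builds μ(E) = line(E) + step·S(E)·[1 + P(E) + χ(k(E))·T(k)]
with S an arctangent of width 1.5 eV centered at 7122 eV, P a slow
post-edge polynomial, and T a low-k taper switching the oscillation on
over k ∈ [1, 2] Å⁻¹. Repeat-scan series add zero-mean Gaussian noise
(default 10⁻³ of the edge step, the magnitude typical of well-averaged
fluorescence data) from one explicit seed, bitwise reproducible.
Pre-edge presets: a five-coordinate-like segment with one Gaussian, and
a six-coordinate-like segment whose second peak sits exactly 2 eV above
the main one.

What the generator does *not* emulate: multiple-scattering paths,
anharmonic (non-Gaussian) disorder, energy-dependent detector effects,
monochromator glitches, self-absorption, and realistic element-specific
scattering phases. Passing tests therefore demonstrate the correctness
and calibration of the inference machinery, not the accuracy of the
analytic scattering stand-ins for real beamline data — for real
analyses, load tabulated ab initio functions.

## Known limitations and observed behaviors

- Fitting the five-coordinate model to six-coordinate synthetic data
  drives the first-shell σ² far below its ligand-free value (the fit
  sharpens shell I to fake the sixth neighbor's amplitude) and the
  model comparison strongly prefers the six-coordinate model. With the
  default k-window (2.5–11 Å⁻¹) the σ² optimum levels off around
  2×10⁻³ Å² rather than contacting a 10⁻³ Å² lower bound; contact
  occurs for shorter windows (k_max ≲ 8.5 Å⁻¹). The near-degeneracy of
  the analytic N and O functions also lets the misspecified fit wash
  out the axial-oxygen shell instead — a compensation channel that
  distinct ab initio phases would price higher.
- The reported χ²ν uses uniform weights in the k-weighted space; with
  white noise in χ this underweights high k relative to a fully
  heteroscedastic treatment. The calibration tests show the effect is
  negligible at the noise levels emulated.
- No multiple-scattering expansion, no R-space (back-transform)
  fitting, no Bayesian refinement, no mmCIF input, no deadtime or
  self-absorption corrections.
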
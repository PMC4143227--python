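# hemexas

Fe K-edge X-ray absorption spectroscopy (XAS) analysis for heme proteins,
built around the question of heme-iron coordination in human serum
heme-albumin: is the ferric iron five-coordinate (the four porphyrin
nitrogens plus the Tyr161 phenoxy oxygen, "4+1") or six-coordinate with an
additional histidine-like nitrogen ("5+1"), as drug binding to the
allosteric FA2 site induces?

The package implements the full inference chain a beamline study of this
question needs, for spectroscopists and structural biologists working from
fluorescence-detected protein XAS:

- **Reduction** of raw scans to the EXAFS oscillation χ(k): fluorescence
  ratio μ = ΣI_f/I₀, repeat-scan averaging with a statistical noise
  estimate, radiation-damage (edge-drift) QC, pre-edge regression line,
  C¹ spline post-edge background, edge-step normalization, E0 at the first
  derivative maximum, k = √(2mₑ(E−E0−ΔE))/ħ (0.2624682 eV⁻¹Å⁻²).
- **Multi-shell EXAFS refinement** in k-space against the Gaussian
  shell sum

  χ(k) = S₀² Σⱼ Nⱼ/(k rⱼ²) |fⱼ(k)| e^(−2σⱼ²k²) e^(−2rⱼ/λ(k)) sin(2krⱼ + φⱼ(k))

  with bounded least squares over the free (Nⱼ, rⱼ, σⱼ², S₀², ΔE),
  reduced-χ² and squared-residual (R²) metrics, MINOS-style asymmetric
  uncertainties from Δχ² = 1 profile scans, bound-pinning diagnostics and
  a 4+1-vs-5+1 model-comparison verdict.
- **Fourier-transform shell analysis**: Hann-windowed transform of
  k-weighted χ(k), peak reading with the ~0.5 Å phase compression of
  light scatterers, and phase-corrected distances.
- **Pre-edge decomposition**: arctangent continuum + 1–2 Gaussians;
  integrated area vs centroid classified against tetra-/penta-/hexa-
  coordinate Fe(III) reference regions (packaged table is a documented
  placeholder).
- **Crystallographic shells**: PDB parsing, Fe-centered neighbor
  extraction, element/distance-window binning, and detection of
  near-collinear Fe–N–C paths that carry strong multiple scattering and
  are excluded from single-scattering fits.
- **Synthetic generator**: forward-modelled raw scans (edge step,
  backgrounds, noise, repeat series) from the published shell models, so
  the whole chain is testable without beamline data.

Fitting follows the model/results idiom of statistical-modelling
packages: `EXAFSModel(chi, shell_model).fit()` returns an `EXAFSResults`
with `summary()`, `conf_interval()`, `plot()` and `compare_models()`.

## Worked example

```python
import numpy as np
from hemexas import (preset_shell_model, default_scattering_map,
                     simulate_chi, fit_shells, fourier_transform, first_peak)

funcs = default_scattering_map()
truth = preset_shell_model("exafs_4plus1")   # refined heme-site geometry
k = np.arange(2.5, 11.0001, 0.05)
chi = simulate_chi(truth, funcs, k)

start = truth
for s in truth.shells:                        # perturb the starting model
    start = start.replace_shell(s.label, r=s.r + 0.05, sigma2=s.sigma2 * 2)
res = fit_shells(chi, start, funcs, noise=1e-3)
print(res.summary())
peak, _ = first_peak(fourier_transform(chi), 0.8, 2.5)
print(f"first FT peak at {peak:.2f} A")
```

prints

```
EXAFS k-space shell refinement
  k-range (2.5, 11.0)  kweight 1  n_data 171  n_free 8
  chi2_reduced 3.792e-30
  R^2 2.381e-32

  shell       el        N    r [A]  sigma2 [A^2]
  I Fe-N      N      4.00    2.070      4.10e-03
  II Fe-O     O      1.00    2.480      1.10e-03
  III Fe-C1   C      8.00    3.090      1.30e-02
  IV Fe-C2    C      4.00    3.500      5.00e-03
  S0^2 0.850   dE 1.35 eV

  free parameter        value     +/- (1 sigma)
  I Fe-N.r                2.0700   -0.0007/+0.0007
  I Fe-N.sigma2           0.0041   -0.0001/+0.0001
  II Fe-O.r               2.4800   -0.0036/+0.0036
  II Fe-O.sigma2          0.0011   -0.0006/+0.0006
  III Fe-C1.r             3.0900   -0.0021/+0.0021
  III Fe-C1.sigma2        0.0130   -0.0004/+0.0004
  IV Fe-C2.r              3.5000   -0.0040/+0.0040
  IV Fe-C2.sigma2         0.0050   -0.0006/+0.0006
first FT peak at 1.58 A
```

(the noiseless refinement recovers every shell of the generating model —
note the compressed axial Fe–O bond at 2.48 Å, vs 2.78 Å in the crystal —
and the first radial-structure peak sits ~0.5 Å below the true 2.07 Å
first-shell distance because of the scattering phase).

A command-line interface mirrors the stages:

```bash
hemexas simulate --preset exafs_4plus1 --n-scans 14 --noise-sd 1e-3
hemexas reduce 'scan_*.dat' --out chi.dat
hemexas fit --chi chi.dat --model shells.cfg
hemexas ft --chi chi.dat
hemexas preedge --scan preedge.dat --n-peaks 2
hemexas shells --pdb structure.pdb
```

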
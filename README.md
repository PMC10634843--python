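# psfinv — inverse modelling of microscope point spread functions

`psfinv` learns an accurate point spread function (PSF) model of a
fluorescence microscope from the data it produces — fluorescent-bead
z-stacks, or directly from the blinking single molecules of an SMLM
(single-molecule localization microscopy) experiment — and uses that model
for maximum-likelihood 3D localization, Cramér–Rao bound (CRLB) analysis and
microscope characterization. It is aimed at SMLM practitioners and
microscope builders who need a PSF calibration that reflects the instrument
*and the sample* (bead size, drift, stage shear, refractive-index mismatch,
field-dependent aberrations, 4Pi interference), not an idealized textbook
PSF.

## The model

Image formation is treated as an inverse problem. The forward model for
emitter *i* with position (xᵢ, yᵢ, zᵢ), photons sᵢ and background bᵢ is

    Uᵢ = ((U_PSF ⊗ g) ⊗ blur, pixel-integrated) · sᵢ + bᵢ

where `g` is the (optional) fluorosphere shape and `U_PSF` one of several
parameterizations:

- **voxel**: a 3D intensity array, shifted to each emitter by Fourier
  phase ramps (model-free, spatial domain);
- **pupil / Zernike**: the scalar diffraction model
  `U_PSF = |𝓕{ A e^{iΦ} · e^{i2πk_z z} · e^{i2π(k_x x + k_y y)} }|²`,
  with pupil magnitude A and phase Φ either free images or Zernike
  expansions `Φ = Σₚ C_p Z_p` (Noll-normalized, coefficients in radians
  RMS; 45 modes through radial order 8), optionally through the full
  vectorial (Richards–Wolf, isotropic-dipole) model with apodization,
  index-mismatch depth aberrations and supercritical-angle emission;
- **IAB 4Pi**: `U(x,y,z,φ) = I + A·cos φ + B·sin φ`, decoupling the
  interference phase φ = 2πkz + φ₀ from the axial envelope;
- **field-dependent**: per-mode Zernike coefficient maps over the field of
  view, bilinearly interpolated at each emitter.

All parameters — the model and every per-emitter nuisance parameter — are
estimated jointly by minimizing the mean square error (voxel models) or the
Poisson negative log-likelihood (pupil-based models) with L-BFGS, using
exact analytic adjoint gradients (one extra FFT per emitter yields the
gradient with respect to every pupil-phase parameter at once). For blinking
data, an iterative loop alternates localization, z-stratified emitter
selection and pupil re-estimation until the pupil stops changing — an
*in situ* PSF measured under exactly the experiment's conditions.

## Worked example

Learn an astigmatic PSF in situ from 100 simulated blinking molecules
(5000 photons each, 10 background photons/pixel), then characterize it:

```python
import numpy as np
from psfinv import (OpticalConfig, SimulationSpec, InsituConfig,
                    simulate_blinking_rois, run_insitu, build_pupil_grid,
                    ZernikePSFModel, characterize, crlb)
from psfinv.psf import field_factors

optics = OpticalConfig(na=1.35, wavelength=660, n_immersion=1.406,
                       pixel_size_xy=120, roi_size=21, oversample=2)
spec = SimulationSpec(config=optics, n_emitters=100, photons=5000,
                      background=10, seed=0, vectorial=False)
rois, truth = simulate_blinking_rois(spec)

result = run_insitu(rois, InsituConfig(n_emitters_target=100, seed=0),
                    optics, seed_aberration={(2, 2): 0.8}, vectorial=False)

grid = build_pupil_grid(optics)
model = ZernikePSFModel(result.pupil, grid,
                        factors=field_factors(grid, optics, vectorial=False))
report = characterize(model)
astig = report.coefficients.query("n == 2 and m == 2").iloc[0]
print(f"recovered {astig['name']}: {astig.coefficient_rad:.3f} rad "
      f"(simulated: 0.800)")
print(f"Strehl ratio: {report.strehl:.3f}")
print(f"lateral FWHM: {report.fwhm_x:.0f} nm")
bounds = crlb(model, (0.0, 0.0, 200.0), photons=5000, background=10)
print(f"CRLB at z=200 nm, 5000 photons: x {bounds['x']:.1f} nm, "
      f"y {bounds['y']:.1f} nm, z {bounds['z']:.1f} nm")
```

Output:

```
recovered vertical astigmatism: 0.801 rad (simulated: 0.800)
Strehl ratio: 0.371
lateral FWHM: 411 nm
CRLB at z=200 nm, 5000 photons: x 1.8 nm, y 3.6 nm, z 5.6 nm
```

The recovered astigmatism matches the simulated ground truth to 0.001 rad;
the Strehl ratio reflects the deliberately introduced 0.8 rad of
z-encoding astigmatism; the CRLB values are the information-limited 3D
localization precisions this PSF supports at that signal level.

## Command line

A thin CLI wraps the same library calls:

```
psfinv simulate     --config config.yaml --out beads.tiff --mode bead
psfinv learn-bead   --config config.yaml --tiff beads.tiff --out model.h5 --model zernike
psfinv learn-insitu --config config.yaml --tiff movie.tiff --out model.h5
psfinv localize     --config config.yaml --tiff movie.tiff --model model.h5 --out locs.csv
psfinv characterize --model model.h5 --out report.json
```

Models are archived as HDF5 (bit-exact round trip), localizations as CSV
with per-axis CRLB columns.

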
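# Methods

This note documents the models implemented in `psfinv`, the assumptions
behind them, the defaults and why they were chosen, and the numerical
decisions a user or maintainer would otherwise have to reverse-engineer
from the code.

## Coordinate and Fourier conventions

All 2D arrays are row-major (y, x); 0-based pixel indices with pixel
centers at integer coordinates; the FOV origin is array index (0, 0).
Frequency grids are centered: the zero-frequency sample sits at index
`floor(N/2)` on each axis, and the matching transforms are
`fftshift ∘ fft2 ∘ ifftshift`. The PSF image origin is the ROI center
pixel `floor(N/2)`, so symmetric PSFs land on a pixel center. Positions
are in nm relative to the ROI center; the phase-ramp sign is fixed (and
unit-tested) so a positive x moves the PSF toward increasing pixel index.
z is in nm, positive meaning the emitter is farther from the objective.

## Pupil-based diffraction model

The frequency grid is conjugate to the (oversampled) image grid, with
sampling `pixel_size / oversample`; construction fails loudly if the
Nyquist extent cannot contain the aperture cutoff NA/λ. The axial
frequency is k_z = √(k² − k_x² − k_y²) with k = n_imm/λ, clamped to zero
outside the propagating support.

Zernike modes carry the Noll RMS normalization (piston ≡ 1, every other
mode unit RMS over the disk), so a phase coefficient is directly its RMS
wavefront contribution in radians and converts to nm by λ/2π. Both Noll
and Fringe orderings are provided; the Fringe table carries named aliases
("vertical astigmatism" = Fringe 5, …, "third-order spherical" =
Fringe 25, a span of 21 modes).

The scalar PSF is |𝓕{A e^{iΦ} · ramps}|², normalized by the Parseval
energy so it integrates to one over the full (oversampled) image plane —
"photons" then means total detected photons when the PSF fits the window.
The vectorial model builds six effective pupils (three dipole orientations
× two detection field components) with Fresnel transmission through the
medium → (optional coverslip) → immersion stack and the geometric rotation
factors of high-NA focusing, then sums intensities incoherently (freely
rotating emitter). At NA ≤ 0.3 it agrees with the scalar model to better
than 1% relative L2, which the tests assert.

**Apodization.** Index-matched: 1/√cos θ (Abbe sine condition, field
amplitude). Mismatched: √cos θ_med / cos θ_imm, a flux-conservation form
chosen so a uniformly emitting source yields a near-uniform retrieved
pupil magnitude. cos θ is clamped at 10⁻³ before inversion so rim samples
stay finite.

**Depth and supercritical-angle emission.** An emitter at depth d above
the coverslip adds phase 2πd(k_z,med − k_z,imm). Frequencies evanescent in
the medium (k_t > n_med/λ) carry supercritical-angle energy at d = 0 and
are attenuated by exp(−2π|Im k_z,med| d) — the simplest physically
monotone decay. The propagating support therefore shrinks to
min(NA, n_med)/λ at depth; for an NA 1.43 oil objective in water the
limiting effective NA is 1.33 (computed by bisection on the continuous
support indicator, not from the discrete grid).

## Forward-model extensions

- **Bead size**: convolution with a uniform sphere, implemented in 3D
  frequency space with the sphere's analytic transform
  3(sin u − u cos u)/u³ — no voxelization error for beads close to the
  voxel size. The real-space voxelization (`bead_kernel`) exists for
  inspection and tests.
- **Extra blur**: 2D Gaussian applied as a frequency-space multiplier,
  differentiable in σ_x, σ_y (fixed or fitted). Order is fixed and
  documented: bead convolution, then blur, then pixel integration.
- **Pixelation**: oversample-and-bin (default oversample 2); binning by
  factor f conserves photons exactly. For factor 5 the binned PSF is well
  approximated by a ~0.2–0.5 px Gaussian blur of the native PSF, which a
  test confirms.
- **Per-frame intensity**: free positive multipliers per frame, on by
  default for pupil-based bead fitting (beads flicker), off for voxel
  fitting.
- **Drift and shear**: frame-wise lateral offsets (fitted or fixed);
  stage-scan shear decomposes a stage step into lateral and axial
  components (dx² + dz² = step², e.g. 50 nm → 40.8 nm lateral +
  28.9 nm axial). Preprocessing removes only the integer-pixel part of
  the shear (photon statistics untouched); the sub-pixel residual is
  passed to the forward model.
- **4Pi (IAB)**: per channel, U = I + A cos φ + B sin φ with
  I = |E_t|² + |E_b|², A_c = 2Re(M e^{iδ_c}), B_c = −2Im(M e^{iδ_c}),
  M = conj(E_t)E_b, and the channel's interferometric offset δ_c folded
  into (A, B). Evaluation at any (z, φ) reproduces the coherent sum
  |E_t + e^{iφ}E_b|² exactly (tested). Default channel offsets are the
  4-channel quadrature {0, π/2, π, 3π/2}; 3-channel {−2π/3, 0, 2π/3}
  layouts are configurable.
- **Field dependence**: per-mode coefficient maps over the FOV; map node
  n sits at the center of its subregion ((n+0.5)·pitch − 0.5 in pixel
  coordinates), queries are bilinear with edge clamping. Default map
  resolution in the FD pipeline is modest (8×8 unless specified) because
  each extra node costs one free parameter per mode.

## Inverse engine

All gradients are exact analytic adjoint (reverse-mode) gradients. For
pupil models the key identity is that the DFT matrix is symmetric, so for
any parameter entering through a real pupil-phase map D,

    dL/dθ = Σ_k S(k) D(k),   S = −2 Im Σ_m G_m P_m,   G_m = 𝓕{q · conj(E_m)},

with q the pixel-wise loss gradient back-propagated through binning, blur
and bead convolution (each self-adjoint or with a trivial adjoint). One
extra FFT per field therefore yields the gradients for *all* Zernike
coefficients, positions and defocus simultaneously; this is what makes
joint fits over hundreds of emitters practical on one CPU. The test suite
verifies every parameter group of every problem class against central
finite differences (relative ≤ 10⁻⁴).

Optimization is L-BFGS (history 10) on a packed parameter vector.
Positivity (photons, backgrounds, voxel values) is enforced by softplus
reparameterization, keeping the problem unconstrained and the gradients
exact — no clipping. Parameter groups can be linked (whole groups) or
tied element-wise (e.g. two beads sharing one z); linked parameters agree
exactly by construction. Each group carries a characteristic scale
(positions 100 nm, photons their median, coefficients 1 rad) to condition
the packed vector. Defaults: max 200 iterations (voxel) / 100–300 (pupil),
relative loss tolerance 10⁻⁷. A NaN loss aborts with the name of the
first offending parameter group.

Losses: MSE for voxel models (the voxel array is not a rate, so Poisson
weighting buys nothing), Poisson NLL Σ(μ − k log μ) for pupil models
(shot-noise-correct, matters at low SNR); non-positive model pixels are
floored at 10⁻⁹ with a warning. Voxel regularizers: second-difference
curvature energy per axis plus a squared-magnitude penalty on the
one-voxel boundary shell (suppresses wraparound aliasing of the Fourier
shifts); FD maps get a first-difference smoothness energy, which also
propagates finite values into emitter-free subregions. Default weights
are zero unless a pipeline sets them; the CLI bead pipeline uses weights
that keep the regularizer near 1% of the initial data term.

Identifiability and gauge. Piston is a global phase; tip/tilt/defocus are
exactly absorbed by per-emitter x, y, z. These four modes are therefore
never fitted as pupil coefficients, and all wavefront-error metrics
project them out. The voxel model has its own gauge: a global shift
(against all positions), a global scale (against photons) and a constant
offset (against backgrounds) leave the data term invariant; comparisons
to ground truth remove exactly these three and nothing else.

## In situ learning loop

Rounds of: localize all candidate ROIs with the current model (Fisher
scoring with coarse z-scan initialization) → quality-filter (minimum
photons 500, maximum background 200 photons/px, drop the worst 10% by
log-likelihood) → stratified selection (equal counts over 10 z-bins of
the configured range, topped up so at least half the subset is defocused,
|z| > 300 nm — defocused emitters carry most of the aberration
information) → joint pupil re-estimation initialized at the current
model. Selection is deterministic under the config seed.

Convergence is declared when the RMS pupil-phase change between rounds
falls below 0.01 rad; with adequate SNR two rounds suffice. Because each
round fits a *different* emitter subset, loss values are not comparable
across rounds; divergence is therefore also judged on the model-change
metric (change growing by more than 50% round-over-round), returning the
previous round's model with a flag.

Astigmatic systems must seed their known astigmatism (default fixtures
use 0.8 rad of vertical astigmatism, which gives a usable ±600 nm
z-range); without it the z-sign is ambiguous in round one. Designed
phase masks (e.g. Tetrapod) can be passed through as an initial phase
image and are projected onto the basis by least squares (the sampled
modes are not exactly orthogonal on a small pupil grid, so plain inner
products would leak between same-parity modes).

The 4Pi variant fits both arm pupils jointly to all channels with
per-emitter (x, y, z, φ) — the interference phase is decoupled from z at
the field level, the same idea as the IAB decomposition — plus optional
per-channel lateral offsets that refine the channel registration
(translation only; the full affine registration is estimated separately
from matched candidate coordinates). Higher-order Zernikes can be linked
between arms. A relative piston phase between the arms is absorbed by the
per-emitter φ. The FD variant replaces the shared coefficient vector by
interpolated maps; gradients accumulate onto map nodes through the
bilinear stencils.

## Localization and characterization

Per-ROI MLE uses Fisher scoring (damped Newton with the Fisher
information as curvature) over (x, y, z[, φ], photons, background),
stopping when every position step falls below 0.01 of its CRLB; a coarse
z (and φ) scan initializes the fit to avoid the astigmatic z-sign
ambiguity. The CRLB comes from the same information matrix,
F_ab = Σ (∂μ/∂a)(∂μ/∂b)/μ, with analytic model derivatives; a singular
matrix raises an error naming the degenerate parameter. On simulation the
localizer attains the bound (empirical std / CRLB ≤ 1.1 at 5000 photons).

Validation uses bias curves: localize every slice of a bead stack and
compare to the linear stage trajectory, after removing each bead's own
mean offset (a bead's absolute position is not an observable of the
model); a frame-dependent residual signals model mismatch. The
characterization report lists named Zernike coefficients, the Strehl
ratio |Σ A e^{iΦ}|²/(Σ A)² (replaced by the interference modulation
depth, median of √(A²+B²)/I over the central 5×5 px of the focal slice,
for 4Pi models) and linearly interpolated FWHMs; voxel-only models report
FWHM with a notice, since no pupil is available.

## Synthetic data

The simulators render through exactly the forward physics the fits use
and add Poisson shot noise. Defaults are the single-molecule benchmark
conditions: 5000 photons per localization (fixed; a log-normal spread of
shape 0.3 is available for realism), 10 background photons per pixel, z
uniform over ±600 nm, 0.8 rad vertical astigmatism plus smaller coma,
trefoil and spherical terms as the ground-truth pupil, 120 nm pixels,
21 px ROIs, λ = 660 nm, NA 1.35 silicone-oil-type immersion (n = 1.406).
Bead stacks add sub-pixel offsets, per-frame intensity jitter, drift
random walks and stage shear as configured; 4Pi data interfere two arm
pupils with per-emitter random cavity phase and k_int = 2n/λ.

What the generator does *not* emulate — and what passing tests therefore
do not demonstrate — includes fluorophore photophysics (on/off kinetics,
bleaching), fixed-dipole emission, camera read noise beyond the
EM-variance approximation (EM counts are halved; an sCMOS per-pixel
variance map can be added as a constant to the Poisson model), sample
structure and autofluorescence background gradients, and optical
misalignments that are not expressible as pupil aberrations. Recovery
results on these fixtures establish correctness of the estimator under
its own model class (plus the stated noise), not robustness to every
real-world deviation.

## Problem sizes

The test suite runs joint fits at reduced scale (3–150 emitters, 13–21 px
ROIs, scalar model and radial order 4 where the property under test does
not require more) so the whole suite completes in a few minutes; the in
situ benchmark itself runs at its stated scale — 250 molecules, vectorial
model, 21 px ROIs, fitting the 21 Fringe modes from vertical astigmatism
through third-order spherical — and recovers the wavefront to well below
1 nm RMS (gauge modes excluded, as they are not observable). The voxel
recovery benchmark uses 20 noise-free beads generated by the voxel
forward model itself, the setting in which exact recovery is the correct
expectation.

## Known limitations

- Voxel models are periodic in all three axes (Fourier shifts); bead
  stacks whose PSF extends past the axial window alias slightly at the
  stack ends. Use enough slices or the pupil model for long-range z.
- The IAB localization z-derivative is piecewise constant (linear
  envelope interpolation); z steps of 25–50 nm keep the resulting CRLB
  error negligible.
- The modified apodization under index mismatch is a stated-property
  construction (near-uniform retrieved magnitude), not derived from a
  rigorous vectorial interface treatment.
- The 4Pi joint fit assumes channels are co-registered to within a pixel
  (it refines translation only) and equal photon splitting across
  channels.
- Gaussian blur and bead convolution are circular in the ROI; ROIs must
  be large enough that wraparound energy is negligible (the default 21 px
  ROI at NA 1.35 is).
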
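"""Scalar and vectorial diffraction PSF generation from pupil functions.

The scalar PSF of an emitter at (x_i, y_i, z_i) is

    U(x - x_i, y - y_i, z_i) = | F{ h * e^{i 2 pi kz z_i} * e^{i 2 pi (kx x_i + ky y_i)} } |^2

with the 2D Fourier transform taken over the pupil. At high NA a scalar field
is insufficient: the vectorial model propagates the three Cartesian field
components of each of three orthogonal dipole orientations through the
medium/(coverslip)/immersion stack, giving six effective pupils whose
intensities are summed incoherently (freely rotating emitter). Both cases are
handled uniformly as a stack of per-field pupil factors.

Sign conventions (fixed by unit test): a positive x_i moves the PSF toward
increasing pixel index; the image origin is the center pixel floor(N/2).
"""

from __future__ import annotations

import numpy as np

from .pupil import ComplexPupil, OpticalConfig, PupilGrid, cfft2

__all__ = [
    "field_factors",
    "pupil_fields",
    "position_phase",
    "psf_from_fields",
    "scalar_psf",
    "vectorial_psf",
]


def field_factors(grid: PupilGrid, config: OpticalConfig | None = None,
                  vectorial: bool = True,
                  coverslip_index: float | None = None) -> np.ndarray:
    """Per-field pupil factors, shape (n_fields, N, N).

    Scalar model: a single factor of ones on the aperture. Vectorial model:
    six factors, one per (field component in {x, y}) x (dipole orientation in
    {x, y, z}), including Fresnel transmission from the sample medium through
    an optional coverslip into the immersion medium and the geometric
    rotation of the field onto the detection polarizations. Supercritical
    angles (evanescent in the medium) yield complex factors whose magnitude
    encodes the near-field coupling.
    """
    cfg = config or grid.config
    ap = grid.aperture
    if not vectorial:
        return np.where(ap, 1.0, 0.0)[None].astype(complex)

    n_i = cfg.n_immersion
    n_m = cfg.n_medium
    sin_i = np.where(ap, grid.kr / cfg.k_immersion, 0.0)
    cos_i = np.sqrt(np.clip(1.0 - sin_i ** 2, 0.0, None))
    # medium-side angle from Snell; may be evanescent (complex cosine)
    sin_m = grid.kr / cfg.k_medium
    cos_m = np.emath.sqrt(1.0 - np.where(ap, sin_m, 0.0) ** 2)

    def fresnel_t(n1, n2, cos1, cos2):
        ts = 2 * n1 * cos1 / (n1 * cos1 + n2 * cos2)
        tp = 2 * n1 * cos1 / (n1 * cos2 + n2 * cos1)
        return ts, tp

    if coverslip_index is None:
        ts, tp = fresnel_t(n_m, n_i, cos_m, cos_i)
    else:
        n_g = coverslip_index
        sin_g = grid.kr / (n_g / cfg.wavelength)
        cos_g = np.emath.sqrt(1.0 - np.where(ap, sin_g, 0.0) ** 2)
        ts1, tp1 = fresnel_t(n_m, n_g, cos_m, cos_g)
        ts2, tp2 = fresnel_t(n_g, n_i, cos_g, cos_i)
        ts, tp = ts1 * ts2, tp1 * tp2

    phi = np.arctan2(grid.ky, grid.kx)
    c, s = np.cos(phi), np.sin(phi)
    fx_px = ts * s ** 2 + tp * c ** 2 * cos_m
    fx_py = (tp * cos_m - ts) * c * s
    fx_pz = -tp * c * sin_m
    fy_px = fx_py
    fy_py = ts * c ** 2 + tp * s ** 2 * cos_m
    fy_pz = -tp * s * sin_m
    fields = np.stack([fx_px, fx_py, fx_pz, fy_px, fy_py, fy_pz]).astype(complex)
    return np.where(ap, fields, 0.0)


def pupil_fields(pupil: ComplexPupil, factors: np.ndarray) -> np.ndarray:
    """Complex per-field pupils A e^{i Phi} * F_m, shape (M, N, N)."""
    return pupil.field()[None] * factors


def position_phase(grid: PupilGrid, x: float, y: float, z: float) -> np.ndarray:
    """Pupil phase ramp (radians) placing an emitter at (x, y, z) nm."""
    return 2 * np.pi * (grid.kx * x + grid.ky * y + grid.kz * z)


def psf_from_fields(fields: np.ndarray, grid: PupilGrid,
                    position=(0.0, 0.0, 0.0),
                    normalization: float | None = None) -> np.ndarray:
    """Incoherent-sum PSF of per-field pupils at an emitter position.

    ``normalization`` defaults to the Parseval energy N^2 * sum |fields|^2 so
    the PSF integrates to 1 over the full (oversampled) grid.
    """
    x, y, z = position
    ramp = np.exp(1j * position_phase(grid, x, y, z))
    e = cfft2(fields * ramp)
    i0 = normalization
    if i0 is None:
        i0 = fields.shape[-1] ** 2 * np.sum(np.abs(fields) ** 2)
    return np.sum(np.abs(e) ** 2, axis=0) / i0


def scalar_psf(pupil: ComplexPupil, grid: PupilGrid,
               position=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Scalar-diffraction PSF image (normalized to unit total energy)."""
    if pupil.magnitude.shape != grid.kx.shape:
        raise ValueError(
            f"pupil shape {pupil.magnitude.shape} != grid {grid.kx.shape}")
    fields = pupil.field()[None]
    return psf_from_fields(fields, grid, position)


def vectorial_psf(pupil: ComplexPupil, grid: PupilGrid,
                  position=(0.0, 0.0, 0.0),
                  config: OpticalConfig | None = None,
                  coverslip_index: float | None = None) -> np.ndarray:
    """Vectorial (isotropic-dipole) PSF image, unit total energy."""
    if pupil.magnitude.shape != grid.kx.shape:
        raise ValueError(
            f"pupil shape {pupil.magnitude.shape} != grid {grid.kx.shape}")
    factors = field_factors(grid, config or grid.config, vectorial=True,
                            coverslip_index=coverslip_index)
    return psf_from_fields(pupil_fields(pupil, factors), grid, position)
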
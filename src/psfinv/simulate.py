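"""Ground-truth simulation of bead stacks, blinking movies and 4Pi data.

Every generator renders through the same forward physics the fits use
(diffraction pupil -> bead/blur -> pixel binning -> photons/background) and
applies Poisson shot noise, so any learned model can be compared against an
exactly known ground truth. Default conditions follow the in situ benchmark:
5000 photons per localization, 10 background photons per pixel, emitter z
uniform over -600..600 nm, and 0.8 rad of vertical astigmatism plus smaller
higher-order aberrations as the ground-truth pupil.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from .forward import (BlurSpec, ShearGeometry, bead_blur_stack,
                      gaussian_blur, pixel_integrate, FieldDependentModel,
                      fd_coeffs_at)
from .psf import field_factors, position_phase
from .pupil import (ComplexPupil, OpticalConfig, PupilGrid, apodization,
                    build_pupil_grid, cfft2, depth_phase)
from .preprocess import ROIDataset
from .zernike import ZernikeBasis

__all__ = [
    "SimulationSpec", "default_aberrations", "make_gt_pupil",
    "simulate_blinking_rois", "simulate_blinking", "simulate_bead_rois",
    "simulate_bead_stack", "simulate_4pi",
]


@dataclass
class SimulationSpec:
    """Conditions of a simulated acquisition.

    Defaults are the single-molecule benchmark conditions (photons fixed at
    5000 per localization, 10 background photons/pixel, z in +-600 nm).
    """

    config: OpticalConfig = dc_field(default_factory=OpticalConfig)
    aberrations: Optional[dict] = None       # {(n, m): rad}, None -> default
    n_emitters: int = 250
    z_range: tuple[float, float] = (-600.0, 600.0)
    photons: float = 5000.0
    fixed_photons: bool = True               # else log-normal, shape 0.3
    background: float = 10.0
    bead_diameter: float = 0.0
    depth: float = 0.0                       # nm above the coverslip
    vectorial: bool = True
    blur: Optional[BlurSpec] = None
    intensity_jitter: float = 0.0            # log-normal sigma per frame
    drift_per_frame: float = 0.0             # nm rms random-walk step
    shear: Optional[ShearGeometry] = None
    fd_model: Optional[FieldDependentModel] = None
    fov_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.photons < 0 or self.background < 0:
            raise ValueError("rates must be >= 0")


def default_aberrations() -> dict:
    """A realistic mixed aberration set for an astigmatic 3D SMLM system.

    0.8 rad vertical astigmatism (the 3D-encoding mode) plus moderate coma,
    trefoil and spherical contributions.
    """
    return {(2, 2): 0.8, (2, -2): 0.05, (3, 1): 0.15, (3, -1): -0.10,
            (4, 0): 0.12, (3, 3): 0.08}


def coeff_vector(basis: ZernikeBasis, aberrations: dict) -> np.ndarray:
    c = np.zeros(basis.n_modes)
    for nm, v in aberrations.items():
        c[basis.index_of(*nm)] = v
    return c


def make_gt_pupil(grid: PupilGrid, basis: ZernikeBasis,
                  aberrations: dict | None = None,
                  with_apodization: bool = True) -> tuple[ComplexPupil,
                                                          np.ndarray]:
    """Ground-truth pupil (apodized magnitude, Zernike phase) + coeff vector."""
    if aberrations is None:
        aberrations = default_aberrations()
    coeffs = coeff_vector(basis, aberrations)
    mag = apodization(grid) if with_apodization else \
        np.where(grid.aperture, 1.0, 0.0)
    phase = basis.compose(coeffs)
    pupil = ComplexPupil(magnitude=mag,
                         phase=np.where(grid.aperture, phase, 0.0),
                         coeff_phase=coeffs, aperture=grid.aperture)
    return pupil, coeffs


class _Renderer:
    """Shared camera-chain renderer for the simulators."""

    def __init__(self, spec: SimulationSpec, grid: PupilGrid,
                 basis: ZernikeBasis):
        self.spec = spec
        self.grid = grid
        self.basis = basis
        cfg = spec.config
        self.factors = field_factors(grid, cfg, vectorial=spec.vectorial)
        mag = apodization(grid)
        if spec.depth > 0:
            dph, damp, _ = depth_phase(spec.depth, grid)
            self.depth_ph = dph
            mag = mag * damp
        else:
            self.depth_ph = 0.0
        self.mag = mag
        self.base = mag * self.factors

    def fields_for(self, coeffs: np.ndarray) -> np.ndarray:
        phase = self.basis.compose(coeffs) + self.depth_ph
        return self.base * np.exp(1j * phase)

    def render(self, fields, x, y, z) -> np.ndarray:
        g = self.grid
        cfg = self.spec.config
        i0 = g.grid_size ** 2 * np.sum(np.abs(self.base) ** 2)
        ramp = np.exp(1j * position_phase(g, x, y, z))
        e = cfft2(fields * ramp)
        psf = np.sum(np.abs(e) ** 2, axis=0) / i0
        if self.spec.blur is not None:
            psf = gaussian_blur(psf, self.spec.blur, g.sample_spacing,
                                cfg.pixel_size_xy)
        return pixel_integrate(psf, cfg.oversample)


def _draw_photons(spec: SimulationSpec, rng, n: int) -> np.ndarray:
    if spec.fixed_photons:
        return np.full(n, spec.photons)
    shape = 0.3
    return spec.photons * rng.lognormal(-shape ** 2 / 2, shape, n)


def simulate_blinking_rois(spec: SimulationSpec, noise: bool = True,
                           max_radial_order: int = 8
                           ) -> tuple[ROIDataset, dict]:
    """Single-molecule ROIs with known ground truth (the in situ benchmark).

    Emitters sit within half a pixel of the ROI center (as after candidate
    detection), z uniform over the configured range. With ``fd_model`` set,
    each emitter receives a random FOV position and its coefficients from the
    maps.
    """
    cfg = spec.config
    rng = np.random.default_rng(spec.seed)
    grid = build_pupil_grid(cfg)
    basis = grid.zernike_basis(max_radial_order=max_radial_order)
    rend = _Renderer(spec, grid, basis)
    gt_coeffs = coeff_vector(basis, spec.aberrations
                             if spec.aberrations is not None
                             else default_aberrations())
    n = spec.n_emitters
    half_px = 0.5 * cfg.pixel_size_xy
    x = rng.uniform(-half_px, half_px, n)
    y = rng.uniform(-half_px, half_px, n)
    z = rng.uniform(*spec.z_range, n)
    s = _draw_photons(spec, rng, n)
    fov = rng.uniform(0, spec.fov_size, (n, 2))
    rois = np.empty((n, cfg.roi_size, cfg.roi_size))
    from .engine import default_fit_mode_indices
    fit_idx = default_fit_mode_indices(basis)
    for i in range(n):
        ci = gt_coeffs.copy()
        if spec.fd_model is not None:
            ci[fit_idx] = ci[fit_idx] + fd_coeffs_at(spec.fd_model, fov[i])
        fields = rend.fields_for(ci)
        mu = rend.render(fields, x[i], y[i], z[i]) * s[i] + spec.background
        rois[i] = rng.poisson(mu) if noise else mu
    origins = np.round(fov[:, ::-1]).astype(int) - cfg.roi_size // 2
    ds = ROIDataset(rois=rois, roi_origin=origins, kind="blinking-emitter",
                    frame_index=np.arange(n))
    gt = {"coeffs": gt_coeffs, "x": x, "y": y, "z": z, "photons": s,
          "background": spec.background, "basis_modes": basis.modes,
          "fov": fov, "seed": spec.seed}
    return ds, gt


def simulate_blinking(spec: SimulationSpec, n_frames: int = 50,
                      emitters_per_frame: float = 5.0,
                      noise: bool = True,
                      min_separation: float | None = None
                      ) -> tuple[np.ndarray, dict]:
    """Sparse-blinking SMLM movie on a full FOV, with ground-truth positions.

    ``min_separation`` (pixels) enforces isolated emitters within a frame by
    rejection sampling; by default emitters may overlap, as in dense raw
    data.
    """
    cfg = spec.config
    rng = np.random.default_rng(spec.seed)
    grid = build_pupil_grid(cfg)
    basis = grid.zernike_basis()
    rend = _Renderer(spec, grid, basis)
    gt_coeffs = coeff_vector(basis, spec.aberrations
                             if spec.aberrations is not None
                             else default_aberrations())
    fields = rend.fields_for(gt_coeffs)
    h = w = spec.fov_size
    movie = np.full((n_frames, h, w), float(spec.background))
    half = cfg.roi_size // 2
    rows = []
    for f in range(n_frames):
        k = rng.poisson(emitters_per_frame)
        placed: list[tuple[float, float]] = []
        for _ in range(k):
            for _try in range(50):
                r = rng.uniform(half + 2, h - half - 3)
                c = rng.uniform(half + 2, w - half - 3)
                if (min_separation is None
                        or all(np.hypot(r - rr, c - cc) >= min_separation
                               for rr, cc in placed)):
                    break
            placed.append((r, c))
            ri, ci = int(np.round(r)), int(np.round(c))
            dx = (c - ci) * cfg.pixel_size_xy
            dy = (r - ri) * cfg.pixel_size_xy
            z = rng.uniform(*spec.z_range)
            s = _draw_photons(spec, rng, 1)[0]
            img = rend.render(fields, dx, dy, z) * s
            movie[f, ri - half:ri + half + 1, ci - half:ci + half + 1] += img
            rows.append((f, c, r, z, s))
    if noise:
        movie = rng.poisson(movie).astype(float)
    gt = {"coeffs": gt_coeffs, "emitters": np.array(rows),
          "columns": ("frame", "x_px", "y_px", "z_nm", "photons"),
          "seed": spec.seed}
    return movie, gt


def simulate_bead_rois(spec: SimulationSpec, n_beads: int = 20,
                       n_slices: int = 25,
                       noise: bool = True) -> tuple[ROIDataset, dict]:
    """Bead-stack ROIs rendered through the full forward chain.

    Each bead receives a random sub-pixel offset and (optionally) per-frame
    intensity jitter, drift and stage-scan shear. Stage z spans
    ``n_slices`` steps of the configured z_step.
    """
    cfg = spec.config
    rng = np.random.default_rng(spec.seed)
    grid = build_pupil_grid(cfg)
    basis = grid.zernike_basis()
    rend = _Renderer(spec, grid, basis)
    gt_coeffs = coeff_vector(basis, spec.aberrations
                             if spec.aberrations is not None
                             else default_aberrations())
    fields = rend.fields_for(gt_coeffs)
    zs = (np.arange(n_slices) - n_slices // 2) * cfg.z_step
    half_px = 0.5 * cfg.pixel_size_xy
    x = rng.uniform(-half_px, half_px, n_beads)
    y = rng.uniform(-half_px, half_px, n_beads)
    z = rng.uniform(-0.4, 0.4, n_beads) * cfg.z_step
    s = _draw_photons(spec, rng, n_beads)
    jitter = (rng.lognormal(0, spec.intensity_jitter, (n_beads, n_slices))
              if spec.intensity_jitter else np.ones((n_beads, n_slices)))
    drift = np.zeros((n_slices, 2))
    if spec.drift_per_frame:
        drift = np.cumsum(rng.normal(0, spec.drift_per_frame,
                                     (n_slices, 2)), axis=0)
    rois = np.empty((n_beads, n_slices, cfg.roi_size, cfg.roi_size))
    for i in range(n_beads):
        stack = []
        for j, zslice in enumerate(zs):
            xj = x[i] + drift[j, 0]
            if spec.shear is not None:
                xj += j * spec.shear.dx_per_step
            stack.append(_render_oversampled(rend, fields, xj,
                                             y[i] + drift[j, 1],
                                             z[i] + zslice))
        psf = np.stack(stack)
        if spec.bead_diameter:
            psf = bead_blur_stack(psf, spec.bead_diameter, cfg.z_step,
                                  grid.sample_spacing)
        if spec.blur is not None:
            psf = gaussian_blur(psf, spec.blur, grid.sample_spacing,
                                cfg.pixel_size_xy)
        binned = pixel_integrate(psf, cfg.oversample)
        mu = binned * (s[i] * jitter[i])[:, None, None] + spec.background
        rois[i] = rng.poisson(mu) if noise else mu
    ds = ROIDataset(rois=rois, roi_origin=np.zeros((n_beads, 2), int),
                    kind="bead-stack", stage_z=zs)
    gt = {"coeffs": gt_coeffs, "x": x, "y": y, "z": z, "photons": s,
          "background": spec.background, "z_slices": zs, "drift": drift,
          "jitter": jitter, "seed": spec.seed}
    return ds, gt


def _render_oversampled(rend: _Renderer, fields, x, y, z) -> np.ndarray:
    g = rend.grid
    i0 = g.grid_size ** 2 * np.sum(np.abs(rend.base) ** 2)
    ramp = np.exp(1j * position_phase(g, x, y, z))
    e = cfft2(fields * ramp)
    return np.sum(np.abs(e) ** 2, axis=0) / i0


def simulate_bead_stack(spec: SimulationSpec, n_beads: int = 10,
                        n_slices: int = 25,
                        noise: bool = True) -> tuple[np.ndarray, dict]:
    """Full-FOV bead z-stack (for detection/cropping tests)."""
    cfg = spec.config
    rng = np.random.default_rng(spec.seed)
    sub = SimulationSpec(**{**spec.__dict__, "n_emitters": n_beads,
                            "seed": spec.seed + 1})
    rois, gt = simulate_bead_rois(sub, n_beads=n_beads, n_slices=n_slices,
                                  noise=False)
    h = w = spec.fov_size
    frames = np.full((n_slices, h, w), float(spec.background))
    half = cfg.roi_size // 2
    centers = []
    placed = []
    for i in range(n_beads):
        for _try in range(100):
            r = rng.integers(half + 2, h - half - 2)
            c = rng.integers(half + 2, w - half - 2)
            if all((r - rr) ** 2 + (c - cc) ** 2 > (3 * half) ** 2
                   for rr, cc in placed):
                break
        placed.append((r, c))
        centers.append((r, c))
        frames[:, r - half:r + half + 1, c - half:c + half + 1] += \
            rois.rois[i] - spec.background
    if noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    gt = dict(gt)
    gt["centers"] = np.array(centers)
    return frames, gt


def simulate_4pi(spec: SimulationSpec,
                 aberrations_top: dict | None = None,
                 aberrations_bottom: dict | None = None,
                 channel_phases: Sequence[float] | None = None,
                 noise: bool = True) -> tuple[np.ndarray, dict]:
    """Multi-channel interferometric 4Pi single-molecule ROIs.

    The two arm pupils interfere coherently; each emitter carries an
    interference phase phi = 2 pi k_int z + phi0 with a random cavity offset
    phi0 per emitter and k_int = 2 n / lambda. Returns (n, C, R, R) data and
    the ground truth.
    """
    cfg = spec.config
    rng = np.random.default_rng(spec.seed)
    grid = build_pupil_grid(cfg)
    basis = grid.zernike_basis()
    if channel_phases is None:
        channel_phases = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
    delta = np.asarray(channel_phases, float)
    mag = np.where(grid.aperture, 1.0, 0.0)
    ct = coeff_vector(basis, aberrations_top
                      if aberrations_top is not None else default_aberrations())
    cb = coeff_vector(basis, aberrations_bottom
                      if aberrations_bottom is not None
                      else {(2, 2): 0.8, (3, 1): -0.1, (4, 0): 0.08})
    phi_t = basis.compose(ct)
    phi_b = basis.compose(cb)
    n = spec.n_emitters
    half_px = 0.5 * cfg.pixel_size_xy
    x = rng.uniform(-half_px, half_px, n)
    y = rng.uniform(-half_px, half_px, n)
    z = rng.uniform(*spec.z_range, n)
    phi0 = rng.uniform(0, 2 * np.pi, n)
    k_int = 2 * cfg.n_immersion / cfg.wavelength
    phi = 2 * np.pi * k_int * z + phi0
    s = _draw_photons(spec, rng, n)
    n2 = grid.grid_size ** 2
    i0 = len(delta) * n2 * 2 * np.sum(mag ** 2)
    data = np.empty((n, len(delta), cfg.roi_size, cfg.roi_size))
    for i in range(n):
        lat = 2 * np.pi * (grid.kx * x[i] + grid.ky * y[i])
        defoc = 2 * np.pi * grid.kz * z[i]
        et = cfft2(mag * np.exp(1j * (phi_t + lat + defoc)))
        eb = cfft2(mag * np.exp(1j * (phi_b + lat - defoc)))
        for ci, d in enumerate(delta):
            f = et + np.exp(1j * (phi[i] + d)) * eb
            psf = np.abs(f) ** 2 / i0
            mu = pixel_integrate(psf, cfg.oversample) * s[i] + spec.background
            data[i, ci] = rng.poisson(mu) if noise else mu
    gt = {"coeffs_top": ct, "coeffs_bottom": cb, "x": x, "y": y, "z": z,
          "phi": phi, "phi0": phi0, "photons": s, "k_int": k_int,
          "channel_phases": delta, "seed": spec.seed}
    return data, gt
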
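"""MLE localization, CRLB, model-validation diagnostics and reports.

Single emitters are localized by maximizing the Poisson likelihood of
``mu = s * PSF(x, y, z) + b`` with Fisher scoring (damped Newton using the
Fisher information in place of the Hessian), which converges to the MLE and
directly yields the Cramer-Rao lower bound from the same information matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forward import (BlurSpec, IAB4PiModel, bead_blur_stack, gaussian_blur,
                      fourier_shift, pixel_integrate)
from .pupil import ComplexPupil, PupilGrid, cfft2, strehl_ratio
from .zernike import fringe_index, mode_name

__all__ = [
    "Localization", "CharacterizationReport",
    "ZernikePSFModel", "VoxelLocModel", "IABLocModel",
    "mle_localize", "crlb", "bias_curve", "fwhm", "modulation_depth",
    "characterize",
]


@dataclass
class Localization:
    """A single fitted emitter."""

    x: float
    y: float
    z: float
    photons: float
    background: float
    crlb_x: float = np.nan
    crlb_y: float = np.nan
    crlb_z: float = np.nan
    log_likelihood: float = np.nan
    frame: int = -1
    channel: int = 0
    fov_x: float = 0.0
    fov_y: float = 0.0
    converged: bool = True
    phi: float = np.nan  # 4Pi interference phase, if applicable


# ---------------------------------------------------------------------------
# PSF models exposing value + position jacobian


class ZernikePSFModel:
    """Pupil-based PSF ready for rendering and localization.

    Wraps a complex pupil (phase from Zernike coefficients or a free image),
    the per-field factors of the scalar/vectorial model and the camera
    sampling chain (optional bead blur, extra Gaussian blur, oversampling and
    binning). ``psf_and_jac`` returns the camera-sampled PSF and its exact
    derivatives with respect to x, y, z via the pupil phase ramps.
    """

    def __init__(self, pupil: ComplexPupil, grid: PupilGrid,
                 factors: np.ndarray | None = None,
                 blur: BlurSpec | None = None,
                 bead_diameter: float = 0.0):
        self.pupil = pupil
        self.grid = grid
        self.cfg = grid.config
        f = pupil.field()
        if factors is None:
            self.fields = f[None]
        else:
            factors = np.asarray(factors, complex)
            self.fields = f[None] * (factors if factors.ndim == 3
                                     else factors[None])
        self.i0 = grid.grid_size ** 2 * np.sum(np.abs(self.fields) ** 2)
        self.blur = blur
        self.bead_diameter = bead_diameter
        self.os = self.cfg.oversample
        self.roi = grid.grid_size // self.os
        self.z_range = (-1500.0, 1500.0)

    n_pos = 3

    def _postprocess(self, imgs: np.ndarray) -> np.ndarray:
        if self.blur is not None:
            imgs = gaussian_blur(imgs, self.blur, self.grid.sample_spacing,
                                 self.cfg.pixel_size_xy)
        return pixel_integrate(imgs, self.os)

    def _raw_and_jac(self, x, y, z):
        g = self.grid
        ph = 2 * np.pi * (g.kx * x + g.ky * y + g.kz * z)
        p = self.fields * np.exp(1j * ph)
        e = cfft2(p)
        psf = np.sum(np.abs(e) ** 2, axis=0) / self.i0
        jac = []
        for d in (g.kx, g.ky, g.kz):
            de = cfft2(p * (2j * np.pi * d))
            jac.append(np.sum(2 * (np.conj(e) * de).real, axis=0) / self.i0)
        return psf, np.stack(jac)

    def psf_and_jac(self, x: float, y: float, z: float):
        if self.bead_diameter:
            half = int(np.ceil(self.bead_diameter / 2 / self.cfg.z_step)) + 2
            zs = np.arange(-half, half + 1) * self.cfg.z_step
            raws, jacs = [], []
            for dz in zs:
                r, j = self._raw_and_jac(x, y, z + dz)
                raws.append(r)
                jacs.append(j)
            stack = bead_blur_stack(np.stack(raws), self.bead_diameter,
                                    self.cfg.z_step, self.grid.sample_spacing)
            jstack = bead_blur_stack(np.stack(jacs, axis=1),
                                     self.bead_diameter, self.cfg.z_step,
                                     self.grid.sample_spacing)
            psf, jac = stack[half], jstack[:, half]
        else:
            psf, jac = self._raw_and_jac(x, y, z)
        return self._postprocess(psf), self._postprocess(jac)

    def psf(self, x: float, y: float, z: float) -> np.ndarray:
        return self.psf_and_jac(x, y, z)[0]

    def stack(self, z_slices: np.ndarray, x: float = 0.0, y: float = 0.0
              ) -> np.ndarray:
        return np.stack([self.psf(x, y, z) for z in z_slices])


class VoxelLocModel:
    """Localization with a voxel PSF: single-frame model by 3D Fourier shift.

    ``psf(x, y, z)`` shifts the volume by (-z, -y, -x) in voxels and returns
    the focal (central) slice; jacobians come from the ramp derivatives.
    """

    n_pos = 3

    def __init__(self, values: np.ndarray, z_step: float, pixel_size: float):
        self.values = np.asarray(values, float)
        self.z_step = z_step
        self.pixel_size = pixel_size
        nz, ny, nx = self.values.shape
        self.fz = np.fft.fftshift(np.fft.fftfreq(nz))[:, None, None]
        self.fy = np.fft.fftshift(np.fft.fftfreq(ny))[None, :, None]
        self.fx = np.fft.fftshift(np.fft.fftfreq(nx))[None, None, :]
        self.vf = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(self.values)))
        zr = (nz // 2 - 1) * z_step
        self.z_range = (-zr, zr)
        self.roi = ny

    def psf_and_jac(self, x, y, z):
        sh = np.exp(-2j * np.pi * (self.fz * (z / self.z_step)
                                   + self.fy * (y / self.pixel_size)
                                   + self.fx * (x / self.pixel_size)))
        vr = self.vf * sh
        j0 = self.values.shape[0] // 2

        def center_slice(f):
            out = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(f))).real
            return out[j0]

        psf = center_slice(vr)
        jac = np.stack([
            center_slice(vr * (-2j * np.pi * self.fx)) / self.pixel_size,
            center_slice(vr * (-2j * np.pi * self.fy)) / self.pixel_size,
            center_slice(vr * (-2j * np.pi * self.fz)) / self.z_step,
        ])
        return psf, jac

    def psf(self, x, y, z):
        return self.psf_and_jac(x, y, z)[0]


class IABLocModel:
    """Localization with an IAB 4Pi model over (x, y, z, phi).

    The envelopes are interpolated linearly in z (piecewise-constant z
    derivative); phi enters analytically through cos/sin. Returns all
    channels stacked.
    """

    n_pos = 4

    def __init__(self, model: IAB4PiModel, pixel_size: float):
        self.m = model
        self.pixel_size = pixel_size
        zax = model.z_axis()
        self.z_range = (zax[0] + 1, zax[-1] - 1)
        self.roi = model.I.shape[-1]

    def psf_and_jac(self, x, y, z, phi):
        m = self.m
        zax = m.z_axis()
        t = np.clip((z - zax[0]) / m.z_step, 0, len(zax) - 1 - 1e-9)
        j0 = int(np.floor(t))
        w = t - j0

        def interp(arr):
            return (1 - w) * arr[:, j0] + w * arr[:, j0 + 1]

        def dz_interp(arr):
            return (arr[:, j0 + 1] - arr[:, j0]) / m.z_step

        c, s = np.cos(phi), np.sin(phi)
        raw = interp(m.I) + interp(m.A) * c + interp(m.B) * s
        draw_z = dz_interp(m.I) + dz_interp(m.A) * c + dz_interp(m.B) * s
        draw_phi = -interp(m.A) * s + interp(m.B) * c
        dxp = x / self.pixel_size
        dyp = y / self.pixel_size

        ny, nx = raw.shape[-2:]
        fy = np.fft.fftshift(np.fft.fftfreq(ny))[:, None]
        fx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :]
        r2 = np.exp(-2j * np.pi * (fy * dyp + fx * dxp))

        def shifted(arr, extra=1.0):
            f = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(
                arr, axes=(-2, -1)), axes=(-2, -1)), axes=(-2, -1))
            out = np.fft.ifft2(np.fft.ifftshift(f * r2 * extra,
                                                axes=(-2, -1)), axes=(-2, -1))
            return np.fft.fftshift(out, axes=(-2, -1)).real

        psf = shifted(raw)
        jx = shifted(raw, extra=-2j * np.pi * fx) / self.pixel_size
        jy = shifted(raw, extra=-2j * np.pi * fy) / self.pixel_size
        jac = np.stack([jx, jy, shifted(draw_z), shifted(draw_phi)])
        return psf, jac

    def psf(self, x, y, z, phi=0.0):
        return self.psf_and_jac(x, y, z, phi)[0]


# ---------------------------------------------------------------------------
# MLE localization and CRLB


def _fisher(mu: np.ndarray, dmu: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, 1e-9)
    flat = dmu.reshape(dmu.shape[0], -1)
    return (flat / mu.ravel()) @ flat.T


def _model_jac(model, theta):
    """mu and dmu/dtheta for theta = (positions..., photons, background)."""
    npos = model.n_pos
    pos, s, b = theta[:npos], theta[npos], theta[npos + 1]
    psf, jac = model.psf_and_jac(*pos)
    mu = s * psf + b
    dmu = np.concatenate([s * jac, psf[None], np.ones_like(psf)[None]])
    return mu, dmu, psf


def _nll(mu, data):
    mu = np.maximum(mu, 1e-9)
    return float(np.sum(mu - data * np.log(mu)))


def mle_localize(roi: np.ndarray, model, start: Sequence[float] | None = None,
                 max_iter: int = 60, z_scan: int = 15) -> Localization:
    """Maximum-likelihood localization of one ROI (photon units).

    ``model`` is any of the *LocModel/ZernikePSFModel wrappers. ``start``
    optionally gives (x, y, z[, phi], photons, background); otherwise moments
    initialize x/y/photons/background and a coarse scan over the model's z
    range (and phi for 4Pi models) picks the starting z, avoiding the
    astigmatic z-sign ambiguity.
    """
    roi = np.asarray(roi, float)
    npos = model.n_pos
    if start is None:
        data2 = roi if roi.ndim == 2 else roi.sum(axis=0)
        b0 = max(float(np.median(data2)), 1e-2)
        s0 = max(float(data2.sum() - b0 * data2.size), 10.0)
        if roi.ndim == 3:
            b0 /= roi.shape[0]
        ny, nx = data2.shape
        yy, xx = np.mgrid[:ny, :nx]
        wts = np.clip(data2 - b0, 0, None)
        wsum = max(wts.sum(), 1e-9)
        px = model.pixel_size if hasattr(model, "pixel_size") else \
            model.cfg.pixel_size_xy
        x0 = (float((wts * xx).sum() / wsum) - nx // 2) * px
        y0 = (float((wts * yy).sum() / wsum) - ny // 2) * px
        zlo, zhi = model.z_range
        zs = np.linspace(zlo * 0.8, zhi * 0.8, z_scan)
        best = None
        phis = [0.0] if npos == 3 else np.linspace(0, 2 * np.pi, 8,
                                                   endpoint=False)
        for zc in zs:
            for ph in phis:
                pos = (x0, y0, zc) if npos == 3 else (x0, y0, zc, ph)
                mu = model.psf(*pos) * s0 + b0
                val = _nll(mu, roi)
                if best is None or val < best[0]:
                    best = (val, pos)
        theta = np.array(list(best[1]) + [s0, b0])
    else:
        theta = np.array(start, float)

    lam = 1e-3
    cur, dmu, _ = _model_jac(model, theta)
    nll = _nll(cur, roi)
    converged = False
    for _ in range(max_iter):
        mu = np.maximum(cur, 1e-9)
        grad = np.array([np.sum((1 - roi / mu) * d) for d in dmu])
        fisher = _fisher(mu, dmu)
        try:
            step = np.linalg.solve(fisher + lam * np.diag(np.diag(fisher))
                                   + 1e-12 * np.eye(len(theta)), grad)
        except np.linalg.LinAlgError:
            break
        ok = False
        for _bt in range(12):
            trial = theta - step
            trial[npos] = max(trial[npos], 1.0)
            trial[npos + 1] = max(trial[npos + 1], 1e-4)
            zlo, zhi = model.z_range
            trial[2] = np.clip(trial[2], zlo, zhi)
            try:
                mu_t, dmu_t, _ = _model_jac(model, trial)
            except Exception:
                step = step / 4
                continue
            nll_t = _nll(mu_t, roi)
            if nll_t <= nll + 1e-9:
                ok = True
                break
            step = step / 4
        if not ok:
            break
        delta = np.abs(theta - trial)
        theta, cur, dmu, nll = trial, mu_t, dmu_t, nll_t
        lam = max(lam / 3, 1e-9)
        crlb_now = np.sqrt(np.abs(np.diag(np.linalg.pinv(
            _fisher(np.maximum(cur, 1e-9), dmu)))))
        if np.all(delta[:npos] < 0.01 * np.maximum(crlb_now[:npos], 1e-3)):
            converged = True
            break

    fisher = _fisher(np.maximum(cur, 1e-9), dmu)
    cov = np.linalg.pinv(fisher)
    sd = np.sqrt(np.abs(np.diag(cov)))
    return Localization(
        x=theta[0], y=theta[1], z=theta[2],
        phi=(theta[3] if npos == 4 else np.nan),
        photons=theta[npos], background=theta[npos + 1],
        crlb_x=sd[0], crlb_y=sd[1], crlb_z=sd[2],
        log_likelihood=-nll, converged=converged)


def crlb(model, position: Sequence[float], photons: float,
         background: float) -> dict[str, float]:
    """Cramer-Rao lower bounds of the Poisson model at given parameters.

    Fisher information F_ab = sum_pixels (dmu/da)(dmu/db)/mu over parameters
    (positions..., photons, background); returns the square roots of the
    inverse diagonal. Raises on a singular information matrix, naming the
    degenerate parameter.
    """
    if photons <= 0:
        raise ValueError("photons must be > 0")
    theta = np.array(list(position) + [photons, background], float)
    mu, dmu, _ = _model_jac(model, theta)
    fisher = _fisher(mu, dmu)
    names = (["x", "y", "z", "phi"][:model.n_pos] + ["photons", "background"])
    if np.linalg.matrix_rank(fisher) < fisher.shape[0]:
        contrib = np.diag(fisher)
        bad = names[int(np.argmin(contrib))]
        raise np.linalg.LinAlgError(
            f"singular Fisher information; degenerate parameter: {bad}")
    cov = np.linalg.inv(fisher)
    sd = np.sqrt(np.diag(cov))
    return dict(zip(names, sd))


# ---------------------------------------------------------------------------
# Validation diagnostics


def bias_curve(bead_rois: np.ndarray, model, z_step: float) -> pd.DataFrame:
    """Per-slice localization bias of bead stacks against linear stage motion.

    Each frame of every bead stack is localized independently with ``model``;
    per bead, the per-frame residual against the linear stage trajectory is
    computed and its own mean removed (the bead's absolute offset is not an
    observable of the model), then averaged across beads. A frame-dependent
    bias in any direction denotes a model mismatch.
    """
    import warnings as _w
    bead_rois = np.asarray(bead_rois, float)
    nb, nz = bead_rois.shape[:2]
    if nb < 2:
        _w.warn("bias_curve with fewer than 2 beads", RuntimeWarning,
                stacklevel=2)
    zst = (np.arange(nz) - nz // 2) * z_step
    res = np.full((nb, nz, 3), np.nan)
    for i in range(nb):
        for j in range(nz):
            loc = mle_localize(bead_rois[i, j], model)
            res[i, j] = (loc.x, loc.y, loc.z - zst[j])
    res -= np.nanmean(res, axis=1, keepdims=True)
    bias = np.nanmean(res, axis=0)
    return pd.DataFrame({"z_stage": zst, "bias_x": bias[:, 0],
                         "bias_y": bias[:, 1], "bias_z": bias[:, 2]})


def fwhm(profile_or_volume: np.ndarray, axis: int = 0,
         spacing: float = 1.0) -> float:
    """Full width at half maximum along an axis through the global peak.

    Half-maximum crossings are located by linear interpolation; raises if the
    profile never falls below half on either side. Invariant under intensity
    rescaling.
    """
    arr = np.asarray(profile_or_volume, float)
    if arr.ndim == 1:
        prof = arr
    else:
        peak = np.unravel_index(np.argmax(arr), arr.shape)
        idx = list(peak)
        idx[axis] = slice(None)
        prof = arr[tuple(idx)]
    i_pk = int(np.argmax(prof))
    half = prof[i_pk] / 2.0
    if prof[i_pk] <= 0:
        raise ValueError("profile has no positive maximum")

    def cross(rng):
        prev = i_pk
        for i in rng:
            if prof[i] <= half:
                f = (prof[prev] - half) / (prof[prev] - prof[i])
                return prev + f * (i - prev)
            prev = i
        raise ValueError("half-maximum crossing not found inside the profile")

    right = cross(range(i_pk + 1, len(prof)))
    left = cross(range(i_pk - 1, -1, -1))
    return float((right - left) * spacing)


def modulation_depth(iab: IAB4PiModel, region: int = 5) -> float:
    """4Pi interference contrast sqrt(A^2+B^2)/I at focus.

    Aggregated as the median over the central ``region`` x ``region`` pixels
    of the focal slice (channel phase offsets do not change the modulus).
    """
    nz = iab.I.shape[1]
    j0 = nz // 2
    ny, nx = iab.I.shape[-2:]
    sl = (0, j0, slice(ny // 2 - region // 2, ny // 2 + region // 2 + 1),
          slice(nx // 2 - region // 2, nx // 2 + region // 2 + 1))
    i_c = iab.I[sl]
    if np.any(i_c <= 0):
        raise ValueError("non-positive envelope in the aggregation region")
    m = np.sqrt(iab.A[sl] ** 2 + iab.B[sl] ** 2) / i_c
    return float(np.median(m))


# ---------------------------------------------------------------------------
# Characterization report


@dataclass
class CharacterizationReport:
    """Summary of a learned PSF model for microscope characterization."""

    coefficients: Optional[pd.DataFrame] = None
    strehl: Optional[float] = None
    modulation: Optional[float] = None
    fwhm_x: Optional[float] = None
    fwhm_y: Optional[float] = None
    fwhm_z: Optional[float] = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"strehl": self.strehl, "modulation_depth": self.modulation,
               "fwhm_x_nm": self.fwhm_x, "fwhm_y_nm": self.fwhm_y,
               "fwhm_z_nm": self.fwhm_z, "notes": list(self.notes)}
        if self.coefficients is not None:
            out["zernike_coefficients"] = self.coefficients.to_dict("records")
        return out


def _coeff_table(modes, coeffs) -> pd.DataFrame:
    rows = []
    for (n, m), c in zip(modes, coeffs):
        f = fringe_index(n, m)
        rows.append({"n": n, "m": m, "fringe": f, "name": mode_name(f),
                     "coefficient_rad": float(c)})
    return pd.DataFrame(rows).sort_values("fringe").reset_index(drop=True)


def characterize(model, z_slices: np.ndarray | None = None,
                 pixel_size: float | None = None) -> CharacterizationReport:
    """Build a characterization report from a learned model.

    Accepts a :class:`ZernikePSFModel` (Zernike/pupil models: coefficient
    table, Strehl, FWHM), a :class:`VoxelLocModel` (FWHM only, with a note
    that no pupil is available) or an :class:`IAB4PiModel` (modulation depth
    replaces the Strehl ratio).
    """
    rep = CharacterizationReport()
    if isinstance(model, IAB4PiModel):
        rep.modulation = modulation_depth(model)
        env = model.I[0]
        for attr, axis, sp in (("fwhm_z", 0, model.z_step),
                               ("fwhm_y", 1, pixel_size or 1.0),
                               ("fwhm_x", 2, pixel_size or 1.0)):
            try:
                setattr(rep, attr, fwhm(env, axis=axis, spacing=sp))
            except ValueError:
                rep.notes.append(f"{attr}: envelope does not reach half "
                                 "maximum inside the sampled volume")
        rep.notes.append("4Pi model: modulation depth reported instead of "
                         "the Strehl ratio")
        return rep
    if isinstance(model, VoxelLocModel):
        v = model.values
        rep.fwhm_x = fwhm(v, axis=2, spacing=model.pixel_size)
        rep.fwhm_y = fwhm(v, axis=1, spacing=model.pixel_size)
        rep.fwhm_z = fwhm(v, axis=0, spacing=model.z_step)
        rep.notes.append("voxel model: no pupil available, report limited "
                         "to FWHM")
        return rep
    # pupil-based
    rep.strehl = strehl_ratio(model.pupil)
    if model.pupil.coeff_phase is not None:
        # modes live on the grid's basis ordering; rebuild names
        basis = model.grid.zernike_basis(
            max_radial_order=_max_order(len(model.pupil.coeff_phase)))
        rep.coefficients = _coeff_table(basis.modes, model.pupil.coeff_phase)
    cfg = model.cfg
    if z_slices is None:
        z_slices = np.arange(-15, 16) * cfg.z_step
    stack = model.stack(z_slices)
    rep.fwhm_x = fwhm(stack, axis=2, spacing=cfg.pixel_size_xy)
    rep.fwhm_y = fwhm(stack, axis=1, spacing=cfg.pixel_size_xy)
    rep.fwhm_z = fwhm(stack, axis=0, spacing=float(z_slices[1] - z_slices[0]))
    return rep


def _max_order(n_modes: int) -> int:
    r = 0
    while (r + 1) * (r + 2) // 2 < n_modes:
        r += 1
    return r
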
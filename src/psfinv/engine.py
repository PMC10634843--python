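"""Gradient-based inverse modelling: joint fits of PSF models to ROI data.

Gradients are exact analytic adjoint (reverse-mode) gradients, derived by
hand for each forward model and verified against central finite differences
in the test suite. The key identity: for a pupil-based model with per-field
pupils P_m, image fields E_m = F{P_m} and PSF sum S = sum_m |E_m|^2 / I0, the
derivative of a loss L with respect to any parameter entering through a real
pupil phase map D (Zernike coefficient, position ramp, defocus) is

    dL/dtheta = sum_k S_map(k) * D(k),   S_map = -2 Im sum_m G_m P_m,

where G_m = F{q conj(E_m)} and q = (dL/dS)/I0, using that the DFT matrix is
symmetric (its transpose equals itself). One extra FFT per field therefore
yields the gradient with respect to *all* phase-type parameters at once,
which is what makes joint fits over hundreds of emitters tractable on a CPU.

Optimization uses L-BFGS (scipy, history 10) on the packed parameter vector
of a :class:`~psfinv.params.ParameterSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from .forward import (BlurSpec, ShearGeometry, bead_blur_stack, gaussian_blur,
                      pixel_integrate, fd_interp_weights, FieldDependentModel)
from .loss import (LossSpec, mse_grad, mse_loss, poisson_grad, poisson_nll,
                   voxel_regularizers, voxel_regularizers_grad,
                   fd_smoothness, fd_smoothness_grad)
from .params import ParameterSet
from .pupil import ComplexPupil, PupilGrid, cfft2
from .zernike import ZernikeBasis

__all__ = [
    "FitError", "FitResult", "fit",
    "PupilFitProblem", "VoxelFitProblem", "FourPiFitProblem",
    "default_fit_mode_indices",
]


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Outcome of a joint fit."""

    values: dict
    final_loss: float
    trace: list
    converged: bool
    n_iter: int
    problem: object = None

    def __post_init__(self):
        # accepted L-BFGS iterates are non-increasing by line-search contract
        pass


def _centered_fftn(a, axes):
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a, axes=axes),
                                       axes=axes), axes=axes)


def _centered_ifftn(a, axes):
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(a, axes=axes),
                                        axes=axes), axes=axes)


def centroid_init(data: np.ndarray, pixel_size: float, z_step: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rough per-ROI (x, y, z) initialization in nm from image moments.

    Lateral: background-subtracted intensity centroid of the frame-summed
    image. Axial: centroid of the per-slice peak prominence (the in-focus
    slice is the sharpest). Good to a fraction of a pixel/step, which is all
    a joint fit needs to start in the right basin.
    """
    data = np.asarray(data, float)
    if data.ndim == 3:
        data = data[:, None]
    n, nf, ny, nx = data.shape
    yy, xx = np.mgrid[:ny, :nx]
    x0 = np.zeros(n)
    y0 = np.zeros(n)
    z0 = np.zeros(n)
    for i in range(n):
        proj = data[i].sum(axis=0)
        w = np.clip(proj - np.median(proj), 0, None)
        ws = max(w.sum(), 1e-9)
        x0[i] = (float((w * xx).sum() / ws) - nx // 2) * pixel_size
        y0[i] = (float((w * yy).sum() / ws) - ny // 2) * pixel_size
        if nf > 1:
            pk = np.array([d.max() - np.median(d) for d in data[i]])
            pk = np.clip(pk - pk.min(), 0, None)
            if pk.sum() > 0:
                z0[i] = (float((pk * np.arange(nf)).sum() / pk.sum())
                         - nf // 2) * z_step
    return x0, y0, z0


def default_fit_mode_indices(basis: ZernikeBasis) -> np.ndarray:
    """Mode indices that are identifiable in a joint pupil fit.

    Piston is a global phase (no effect on the PSF) and tip/tilt/defocus are
    gauge-degenerate with the emitters' x, y, z, so they are excluded; the
    fitted set starts at astigmatism.
    """
    skip = {(0, 0), (1, 1), (1, -1), (2, 0)}
    return np.array([i for i, nm in enumerate(basis.modes) if nm not in skip])


def _data_term(name):
    if name == "poisson":
        return poisson_nll, poisson_grad
    return mse_loss, mse_grad


def _check_finite(grads: dict, loss: float):
    if np.isfinite(loss) and all(np.all(np.isfinite(g)) for g in grads.values()):
        return
    bad = [n for n, g in grads.items() if not np.all(np.isfinite(g))]
    raise FitError("non-finite loss/gradient; first offending parameter "
                   f"group: {bad[0] if bad else 'loss (all gradients finite)'}")


def fit(problem, params: ParameterSet | None = None, max_iter: int = 100,
        ftol: float = 1e-7, history: int = 10) -> FitResult:
    """Minimize a problem's loss with L-BFGS; returns the fit result.

    ``problem`` must expose ``make_params()`` and
    ``objective(params) -> (loss, packed_grad)``.
    """
    if params is None:
        params = problem.make_params()
    theta0 = params.pack()
    trace: list[float] = []
    state = {"f": None}

    def fun(theta):
        f, g = problem.objective_packed(params, theta)
        state["f"] = f
        return f, g

    def cb(_):
        trace.append(state["f"])

    res = scipy.optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": max_iter, "ftol": ftol, "maxcor": history,
                 "maxls": 40})
    params.unpack(res.x)
    return FitResult(values=params.values(), final_loss=float(res.fun),
                     trace=trace, converged=bool(res.success),
                     n_iter=int(res.nit), problem=problem)


# ---------------------------------------------------------------------------
# Pupil-based joint fit


class PupilFitProblem:
    """Joint Zernike/pupil-image fit of many ROIs (beads or single molecules).

    Data layout: (n_roi, n_frames, R, R) in photons; single-molecule data use
    n_frames = 1. All emitters share the pupil (or, with ``fd_model`` set,
    draw their Zernike coefficients from field-dependent maps interpolated at
    their FOV positions); positions, photons and backgrounds are free per
    emitter (photons per frame when ``per_frame_intensity``).
    """

    def __init__(self, data: np.ndarray, grid: PupilGrid, basis: ZernikeBasis,
                 factors: np.ndarray,
                 magnitude: np.ndarray | None = None,
                 fit_mode_idx: np.ndarray | None = None,
                 fixed_coeffs: np.ndarray | None = None,
                 z_slices: np.ndarray | None = None,
                 shear: ShearGeometry | None = None,
                 frame_dx: np.ndarray | None = None,
                 bead_diameter: float = 0.0,
                 blur: BlurSpec | None = None,
                 fit_blur: bool = False,
                 per_frame_intensity: bool = False,
                 loss_spec: LossSpec | None = None,
                 fd_model: FieldDependentModel | None = None,
                 fov_positions: np.ndarray | None = None,
                 fit_magnitude: bool = False,
                 depth_amplitude: np.ndarray | None = None,
                 chunk_elems: int = 6_000_000):
        data = np.asarray(data, float)
        if data.ndim == 3:
            data = data[:, None]
        self.data = data
        self.n_roi, self.n_frames, self.roi, _ = data.shape
        self.grid = grid
        self.cfg = grid.config
        self.os = self.cfg.oversample
        if grid.grid_size != self.roi * self.os:
            raise ValueError("grid size must equal roi_size * oversample")
        self.basis = basis
        if magnitude is None:
            magnitude = np.where(grid.aperture, 1.0, 0.0)
        if depth_amplitude is not None:
            magnitude = magnitude * depth_amplitude
        self.magnitude = magnitude
        self.factors = np.asarray(factors, complex)
        if self.factors.ndim == 2:
            self.factors = self.factors[None]
        self.fit_idx = (default_fit_mode_indices(basis)
                        if fit_mode_idx is None else np.asarray(fit_mode_idx))
        self.zfit = basis.values[self.fit_idx]
        self.fixed_coeffs = (np.zeros(basis.n_modes) if fixed_coeffs is None
                             else np.asarray(fixed_coeffs, float))
        self.phi_fixed = basis.compose(self.fixed_coeffs)
        self.z_slices = (np.zeros(self.n_frames) if z_slices is None
                         else np.asarray(z_slices, float))
        if frame_dx is not None:
            self.shear_dx = np.asarray(frame_dx, float)
        elif shear is not None:
            self.shear_dx = np.array([j * shear.dx_per_step
                                      for j in range(self.n_frames)])
        else:
            self.shear_dx = np.zeros(self.n_frames)
        self.bead_diameter = bead_diameter
        self.blur = blur
        self.fit_blur = fit_blur
        self.per_frame = per_frame_intensity
        self.loss_spec = loss_spec or LossSpec()
        self.fd_model = fd_model
        self.fit_magnitude = fit_magnitude
        if fd_model is not None:
            if fov_positions is None:
                raise ValueError("fd_model requires per-ROI fov_positions")
            self._fd_stencils = [fd_interp_weights(fd_model, p)
                                 for p in np.asarray(fov_positions, float)]
            if fd_model.maps.shape[0] != len(self.fit_idx):
                raise ValueError("fd maps must cover exactly the fitted modes")
        n = grid.grid_size
        self.n2 = n * n
        nf = self.factors.shape[0] * self.n_frames * self.n2
        self.chunk = max(1, int(chunk_elems // max(nf, 1)))

    # -- parameters ---------------------------------------------------------

    def make_params(self, coeffs0=None, x0=None, y0=None, z0=None,
                    photons0=None, background0=None,
                    link_positions: bool = False) -> ParameterSet:
        ps = ParameterSet()
        nr = self.n_roi
        if self.fd_model is not None:
            maps0 = (self.fd_model.maps if coeffs0 is None else coeffs0)
            ps.add("fd_maps", np.asarray(maps0, float))
        else:
            c0 = (np.zeros(len(self.fit_idx)) if coeffs0 is None
                  else np.asarray(coeffs0, float))
            ps.add("coeffs", c0)
        ps.add("x", np.zeros(nr) if x0 is None else x0, scale=100.0)
        ps.add("y", np.zeros(nr) if y0 is None else y0, scale=100.0)
        ps.add("z", np.zeros(nr) if z0 is None else z0, scale=100.0)
        if photons0 is None:
            s0 = np.clip(self.data.sum(axis=(-2, -1))
                         - self.roi ** 2 * np.median(self.data, axis=(-2, -1)),
                         10.0, None)
            photons0 = s0 if self.per_frame else s0.mean(axis=1)
        photons0 = np.asarray(photons0, float)
        ps.add("photons", photons0, positive=True,
               scale=float(max(np.median(photons0), 1.0)))
        if background0 is None:
            background0 = np.maximum(
                np.median(self.data, axis=(1, 2, 3)), 0.01)
        ps.add("background", np.asarray(background0, float), positive=True,
               scale=float(max(np.median(background0), 0.1)))
        if self.fit_magnitude:
            m0 = np.zeros(len(self.fit_idx) + 1)
            m0[0] = 1.0  # piston of the magnitude expansion
            ps.add("mag_coeffs", m0)
        if self.fit_blur:
            b = self.blur or BlurSpec(0.3, 0.3)
            ps.add("blur_sigma", np.array([max(b.sigma_x, 1e-2),
                                           max(b.sigma_y, 1e-2)]),
                   positive=True, scale=0.5)
        return ps

    # -- coefficients per ROI ----------------------------------------------

    def _roi_coeffs(self, vals) -> np.ndarray:
        if self.fd_model is None:
            return np.broadcast_to(vals["coeffs"],
                                   (self.n_roi, len(self.fit_idx)))
        maps = vals["fd_maps"]
        out = np.zeros((self.n_roi, len(self.fit_idx)))
        for i, st in enumerate(self._fd_stencils):
            for iy, ix, w in st:
                out[i] += w * maps[:, iy, ix]
        return out

    def _coeff_backward(self, dC: np.ndarray, vals, grads: dict):
        if self.fd_model is None:
            grads["coeffs"] = grads.get("coeffs", 0) + dC.sum(axis=0)
            return
        dmaps = np.zeros_like(vals["fd_maps"])
        for i, st in enumerate(self._fd_stencils):
            for iy, ix, w in st:
                dmaps[:, iy, ix] += w * dC[i]
        grads["fd_maps"] = grads.get("fd_maps", 0) + dmaps

    # -- objective ----------------------------------------------------------

    def objective_packed(self, params: ParameterSet, theta: np.ndarray):
        vals = params.unpack(theta)
        loss, grads = self.objective(vals)
        _check_finite(grads, loss)
        return loss, params.pack_grad(grads)

    def _magnitude_field(self, vals):
        """Current magnitude map and (optionally) its Zernike jacobian parts."""
        if not self.fit_magnitude:
            return self.magnitude, None
        mc = vals["mag_coeffs"]
        zmag = np.concatenate([self.basis.values[:1],
                               self.basis.values[self.fit_idx]])
        amap = np.tensordot(mc, zmag, axes=(0, 0))
        mag = self.magnitude * np.clip(amap, 0.0, None)
        return mag, (zmag, amap)

    def objective(self, vals) -> tuple[float, dict]:
        lf, lg = _data_term(self.loss_spec.data_term)
        grid = self.grid
        n = grid.grid_size
        coeffs = self._roi_coeffs(vals)
        x, y, z = vals["x"], vals["y"], vals["z"]
        s = vals["photons"]
        if not self.per_frame:
            s = np.broadcast_to(s[:, None], (self.n_roi, self.n_frames))
        b = vals["background"]
        blur = self.blur
        if self.fit_blur:
            bs = vals["blur_sigma"]
            blur = BlurSpec(float(bs[0]), float(bs[1]))
        mag, mag_jac = self._magnitude_field(vals)
        base = mag * self.factors            # (M, N, N)
        i0 = self.n2 * np.sum(np.abs(base) ** 2)

        ntot = self.data.size
        loss = 0.0
        dC = np.zeros_like(coeffs)
        gx = np.zeros(self.n_roi)
        gy = np.zeros(self.n_roi)
        gz = np.zeros(self.n_roi)
        gs = np.zeros((self.n_roi, self.n_frames))
        gb = np.zeros(self.n_roi)
        gsig = np.zeros(2)
        t_real_acc = np.zeros((n, n))    # sum over rois/frames of 2 Re(T)
        di0_acc = 0.0                    # dL/dI0 (normalization path)
        kx2p = 2 * np.pi * grid.kx
        ky2p = 2 * np.pi * grid.ky
        kz2p = 2 * np.pi * grid.kz

        for lo in range(0, self.n_roi, self.chunk):
            hi = min(lo + self.chunk, self.n_roi)
            nc = hi - lo
            phi_ab = (self.phi_fixed
                      + np.tensordot(coeffs[lo:hi], self.zfit, axes=(1, 0)))
            x_eff = x[lo:hi, None] + self.shear_dx[None, :]
            z_eff = z[lo:hi, None] + self.z_slices[None, :]
            ph = (kx2p[None, None] * x_eff[..., None, None]
                  + ky2p[None, None] * y[lo:hi, None, None, None]
                  + kz2p[None, None] * z_eff[..., None, None])
            pupils = base[None, None] * np.exp(
                1j * (phi_ab[:, None, None] + ph[:, :, None]))
            e = cfft2(pupils)
            psf = np.sum(np.abs(e) ** 2, axis=2) / i0   # (nc, nf, N, N)
            pre_blur = None
            if self.bead_diameter:
                psf = bead_blur_stack(psf, self.bead_diameter,
                                      self.cfg.z_step, grid.sample_spacing)
            if blur is not None and (blur.sigma_x or blur.sigma_y):
                pre_blur = psf
                psf = gaussian_blur(psf, blur, grid.sample_spacing,
                                    self.cfg.pixel_size_xy)
            binned = pixel_integrate(psf, self.os)
            model = (binned * s[lo:hi, :, None, None]
                     + b[lo:hi, None, None, None])
            d = self.data[lo:hi]
            loss += lf(model, d) * model.size / ntot
            w = lg(model, d) * model.size / ntot

            gs[lo:hi] = np.sum(w * binned, axis=(-2, -1))
            gb[lo:hi] = np.sum(w, axis=(1, 2, 3))
            dbinned = w * s[lo:hi, :, None, None]
            dpsf = np.repeat(np.repeat(dbinned, self.os, axis=-2),
                             self.os, axis=-1)
            if blur is not None and (blur.sigma_x or blur.sigma_y):
                if self.fit_blur:
                    gsig += _blur_sigma_grad(pre_blur, dpsf, blur,
                                             grid.sample_spacing,
                                             self.cfg.pixel_size_xy)
                dpsf = gaussian_blur(dpsf, blur, grid.sample_spacing,
                                     self.cfg.pixel_size_xy)
            if self.bead_diameter:
                dpsf = bead_blur_stack(dpsf, self.bead_diameter,
                                       self.cfg.z_step, grid.sample_spacing)
            q = dpsf / i0
            g_fields = cfft2(q[:, :, None] * np.conj(e))
            t = np.sum(g_fields * pupils, axis=2)       # (nc, nf, N, N)
            smap = -2.0 * t.imag
            if self.fit_magnitude:
                t_real_acc += 2.0 * t.real.sum(axis=(0, 1))
                di0_acc += -np.sum(q * np.sum(np.abs(e) ** 2, axis=2)) / i0
            gx[lo:hi] = np.einsum("ijkl,kl->i", smap, kx2p)
            gy[lo:hi] = np.einsum("ijkl,kl->i", smap, ky2p)
            gz[lo:hi] = np.einsum("ijkl,kl->i", smap, kz2p)
            dC[lo:hi] = np.tensordot(smap.sum(axis=1), self.zfit,
                                     axes=([-2, -1], [-2, -1]))

        grads: dict[str, np.ndarray] = {"x": gx, "y": gy, "z": gz,
                                        "background": gb}
        grads["photons"] = gs if self.per_frame else gs.sum(axis=1)
        self._coeff_backward(dC, vals, grads)
        if self.fit_magnitude:
            # A_total = A_base * relu(sum mc_p Zmag_p); two gradient paths:
            # through the pupils (t_real_acc) and through I0 (di0_acc)
            zmag, amap = mag_jac
            w2 = np.sum(np.abs(self.factors) ** 2, axis=0)
            active = (amap > 0) & (self.magnitude > 1e-12)
            safe_inv = np.where(mag > 1e-12,
                                1.0 / np.where(mag > 1e-12, mag, 1.0), 0.0)
            field = np.where(
                active,
                t_real_acc * self.magnitude * safe_inv
                + di0_acc * self.n2 * 2.0 * mag * w2 * self.magnitude,
                0.0)
            grads["mag_coeffs"] = np.tensordot(field, zmag,
                                               axes=([-2, -1], [-2, -1]))
        if self.fit_blur:
            grads["blur_sigma"] = gsig
        if self.fd_model is not None and self.loss_spec.fd_smooth_weight:
            wgt = self.loss_spec.fd_smooth_weight
            loss += wgt * fd_smoothness(vals["fd_maps"])
            grads["fd_maps"] = (grads["fd_maps"]
                                + wgt * fd_smoothness_grad(vals["fd_maps"]))
        return float(loss), grads

    # -- results ------------------------------------------------------------

    def full_coeffs(self, vals) -> np.ndarray:
        out = self.fixed_coeffs.copy()
        if self.fd_model is None:
            out[self.fit_idx] += vals["coeffs"]
        return out

    def result_pupil(self, vals) -> ComplexPupil:
        phase = self.phi_fixed.copy()
        if self.fd_model is None:
            phase = self.basis.compose(self.full_coeffs(vals))
        mag, _ = self._magnitude_field(vals)
        return ComplexPupil(magnitude=mag, phase=np.where(
            self.grid.aperture, phase, 0.0), aperture=self.grid.aperture,
            coeff_phase=(self.full_coeffs(vals)
                         if self.fd_model is None else None),
            magnitude_mode="zernike" if self.fit_magnitude else "constant")


def _blur_sigma_grad(pre_blur, dpsf, blur, spacing, pixel_size):
    """d loss / d (sigma_x, sigma_y) of the extra-blur kernel."""
    ny, nx = pre_blur.shape[-2:]
    ky = np.fft.fftfreq(ny, d=spacing)[:, None]
    kx = np.fft.fftfreq(nx, d=spacing)[None, :]
    sx = blur.sigma_x * pixel_size
    sy = blur.sigma_y * pixel_size
    g = np.exp(-2 * np.pi ** 2 * ((sx * kx) ** 2 + (sy * ky) ** 2))
    f = np.fft.fft2(pre_blur, axes=(-2, -1))
    out = np.zeros(2)
    for i, dg in enumerate((
            g * (-4 * np.pi ** 2 * sx * kx ** 2) * pixel_size,
            g * (-4 * np.pi ** 2 * sy * ky ** 2) * pixel_size)):
        der = np.fft.ifft2(f * dg, axes=(-2, -1)).real
        out[i] = np.sum(dpsf * der)
    return out


# ---------------------------------------------------------------------------
# Voxel joint fit


class VoxelFitProblem:
    """Joint fit of a voxel PSF and per-bead parameters to bead stacks.

    Forward model: the shared voxel array (positivity via softplus) is
    shifted to each bead's position by 3D Fourier phase ramps, scaled by the
    bead's photons (optionally per frame) and offset by its background. The
    loss is the MSE plus curvature/edge regularizers.
    """

    def __init__(self, data: np.ndarray, z_step: float, pixel_size: float,
                 loss_spec: LossSpec | None = None,
                 per_frame_intensity: bool = False,
                 fit_drift: bool = False):
        self.data = np.asarray(data, float)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_roi, nz, R, R)")
        self.n_roi, self.nz, self.roi, _ = self.data.shape
        self.z_step = z_step
        self.pixel_size = pixel_size
        self.loss_spec = loss_spec or LossSpec(data_term="mse")
        self.per_frame = per_frame_intensity
        self.fit_drift = fit_drift
        fz = np.fft.fftshift(np.fft.fftfreq(self.nz))
        fy = np.fft.fftshift(np.fft.fftfreq(self.roi))
        self.fz = fz[:, None, None]
        self.fy = fy[None, :, None]
        self.fx = fy[None, None, :]

    def make_params(self, init_voxels: float | np.ndarray = 1e-3,
                    x0=None, y0=None, z0=None, photons0=None,
                    background0=None, fix_background: bool = False,
                    tie: dict | None = None) -> ParameterSet:
        ps = ParameterSet()
        v0 = (np.full((self.nz, self.roi, self.roi), float(init_voxels))
              if np.isscalar(init_voxels) else np.asarray(init_voxels, float))
        ps.add("voxels", v0, positive=True)
        nr = self.n_roi
        tie = tie or {}
        ps.add("x", np.zeros(nr) if x0 is None else x0, scale=100.0,
               tie=tie.get("x"))
        ps.add("y", np.zeros(nr) if y0 is None else y0, scale=100.0,
               tie=tie.get("y"))
        ps.add("z", np.zeros(nr) if z0 is None else z0, scale=100.0,
               tie=tie.get("z"))
        if photons0 is None:
            bg_est = np.median(self.data, axis=(-2, -1))[..., None, None]
            s0 = np.clip((self.data - bg_est).sum(axis=(-2, -1)), 10, None)
            photons0 = s0 if self.per_frame else s0.mean(axis=1)
        ps.add("photons", photons0, positive=True,
               scale=float(np.median(photons0)))
        if background0 is None:
            background0 = np.maximum(np.median(self.data, axis=(1, 2, 3)),
                                     1e-3)
        ps.add("background", background0, positive=True,
               free=not fix_background,
               scale=float(max(np.median(background0), 1e-3)))
        if self.fit_drift:
            ps.add("drift", np.zeros((self.nz, 2)), scale=10.0)
        return ps

    def objective_packed(self, params: ParameterSet, theta: np.ndarray):
        vals = params.unpack(theta)
        loss, grads = self.objective(vals)
        _check_finite(grads, loss)
        return loss, params.pack_grad(grads)

    def _ramp(self, dz, dy, dx):
        return np.exp(-2j * np.pi * (self.fz * dz + self.fy * dy
                                     + self.fx * dx))

    @staticmethod
    def _shift2(img: np.ndarray, dx: float, dy: float, fy, fx,
                conj: bool = False) -> np.ndarray:
        sgn = 2j if conj else -2j
        f2 = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
        r2 = np.exp(sgn * np.pi * (fy * dy + fx * dx))
        return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(f2 * r2))).real

    def objective(self, vals):
        v = vals["voxels"]
        x, y, z = vals["x"], vals["y"], vals["z"]
        s = vals["photons"]
        if not self.per_frame:
            s = np.broadcast_to(s[:, None], (self.n_roi, self.nz))
        b = vals["background"]
        drift = vals.get("drift")
        fy2, fx2 = self.fy[0], self.fx[0]
        axes = (-3, -2, -1)
        vf = _centered_fftn(v, axes)
        ntot = self.data.size
        loss = 0.0
        gv = np.zeros_like(v)
        gx = np.zeros(self.n_roi)
        gy = np.zeros(self.n_roi)
        gz = np.zeros(self.n_roi)
        gs = np.zeros((self.n_roi, self.nz))
        gb = np.zeros(self.n_roi)
        gdrift = np.zeros((self.nz, 2)) if self.fit_drift else None
        for i in range(self.n_roi):
            dxv = x[i] / self.pixel_size
            dyv = y[i] / self.pixel_size
            dzv = z[i] / self.z_step
            ramp = self._ramp(dzv, dyv, dxv)
            vr = vf * ramp
            shifted3 = _centered_ifftn(vr, axes).real
            if drift is not None:
                shifted = np.stack([
                    self._shift2(shifted3[j], drift[j, 0] / self.pixel_size,
                                 drift[j, 1] / self.pixel_size, fy2, fx2)
                    for j in range(self.nz)])
            else:
                shifted = shifted3
            model = shifted * s[i][:, None, None] + b[i]
            r = 2.0 * (model - self.data[i]) / ntot
            loss += float(np.sum((model - self.data[i]) ** 2)) / ntot
            gs[i] = np.sum(r * shifted, axis=(-2, -1))
            gb[i] = np.sum(r)
            g_shift = r * s[i][:, None, None]
            if drift is not None:
                g3 = np.empty_like(g_shift)
                for j in range(self.nz):
                    ddx = drift[j, 0] / self.pixel_size
                    ddy = drift[j, 1] / self.pixel_size
                    g3[j] = self._shift2(g_shift[j], ddx, ddy, fy2, fx2,
                                         conj=True)
                    if self.fit_drift:
                        f2 = np.fft.fftshift(np.fft.fft2(
                            np.fft.ifftshift(shifted3[j])))
                        r2 = np.exp(-2j * np.pi * (fy2 * ddy + fx2 * ddx))
                        for axi, fr in ((0, fx2), (1, fy2)):
                            der = np.fft.fftshift(np.fft.ifft2(
                                np.fft.ifftshift(
                                    f2 * r2 * (-2j * np.pi * fr)))).real
                            gdrift[j, axi] += np.sum(
                                g_shift[j] * der) / self.pixel_size
            else:
                g3 = g_shift
            gf = _centered_fftn(g3, axes)
            gv += _centered_ifftn(gf * np.conj(ramp), axes).real
            # position gradients: derivative of the 3D ramp phase
            for garr, freq, scale in ((gx, self.fx, self.pixel_size),
                                      (gy, self.fy, self.pixel_size),
                                      (gz, self.fz, self.z_step)):
                der = _centered_ifftn(vr * (-2j * np.pi * freq), axes).real
                garr[i] = np.sum(g3 * der) / scale
        grads = {"voxels": gv, "x": gx, "y": gy, "z": gz, "background": gb}
        if self.fit_drift:
            grads["drift"] = gdrift
        grads["photons"] = gs if self.per_frame else gs.sum(axis=1)
        ls = self.loss_spec
        if ls.smooth_weight or ls.edge_weight:
            loss += voxel_regularizers(v, ls.smooth_weight, ls.edge_weight)
            grads["voxels"] = grads["voxels"] + voxel_regularizers_grad(
                v, ls.smooth_weight, ls.edge_weight)
        return float(loss), grads

    def result_voxels(self, vals) -> np.ndarray:
        return vals["voxels"]


# ---------------------------------------------------------------------------
# 4Pi coherent two-arm joint fit


class FourPiFitProblem:
    """Joint fit of the two arm pupils of a 4Pi microscope to multi-channel
    single-molecule (or bead) ROIs.

    The channel-c field of emitter i is E_t + e^{i(phi_i + d_c)} E_b with
    arm fields built from Zernike-parameterized top/bottom pupils; the
    emitter's interference phase phi_i is fitted independently of its z
    (the I/A/B decoupling expressed at the field level). Higher-order
    Zernikes can be linked between the arms; per-channel lateral offsets
    refine the channel registration.
    """

    def __init__(self, data: np.ndarray, grid: PupilGrid, basis: ZernikeBasis,
                 magnitude: np.ndarray | None = None,
                 fit_mode_idx: np.ndarray | None = None,
                 channel_phases: Sequence[float] | None = None,
                 loss_spec: LossSpec | None = None,
                 link_arms: bool = False,
                 fit_channel_offsets: bool = False,
                 chunk_elems: int = 4_000_000):
        self.data = np.asarray(data, float)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_roi, n_channels, R, R)")
        self.n_roi, self.n_ch, self.roi, _ = self.data.shape
        self.grid = grid
        self.cfg = grid.config
        self.os = self.cfg.oversample
        if grid.grid_size != self.roi * self.os:
            raise ValueError("grid size must equal roi_size * oversample")
        self.basis = basis
        self.magnitude = (np.where(grid.aperture, 1.0, 0.0)
                          if magnitude is None else magnitude)
        self.fit_idx = (default_fit_mode_indices(basis)
                        if fit_mode_idx is None else np.asarray(fit_mode_idx))
        self.zfit = basis.values[self.fit_idx]
        if channel_phases is None:
            channel_phases = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
        if len(channel_phases) != self.n_ch:
            raise ValueError(
                f"{len(channel_phases)} channel phases for {self.n_ch} channels")
        self.delta = np.asarray(channel_phases, float)
        self.loss_spec = loss_spec or LossSpec()
        self.link_arms = link_arms
        self.fit_offsets = fit_channel_offsets
        n = grid.grid_size
        self.n2 = n * n
        self.i0 = self.n_ch * self.n2 * 2 * np.sum(self.magnitude ** 2)
        self.chunk = max(1, int(chunk_elems // (self.n_ch * self.n2)))

    def make_params(self, coeffs_top0=None, coeffs_bottom0=None, x0=None,
                    y0=None, z0=None, phi0=None, photons0=None,
                    background0=None) -> ParameterSet:
        ps = ParameterSet()
        p = len(self.fit_idx)
        link = "arms" if self.link_arms else None
        ps.add("coeffs_top",
               np.zeros(p) if coeffs_top0 is None else coeffs_top0, link=link)
        ps.add("coeffs_bottom",
               np.zeros(p) if coeffs_bottom0 is None else coeffs_bottom0,
               link=link)
        nr = self.n_roi
        ps.add("x", np.zeros(nr) if x0 is None else x0, scale=100.0)
        ps.add("y", np.zeros(nr) if y0 is None else y0, scale=100.0)
        ps.add("z", np.zeros(nr) if z0 is None else z0, scale=100.0)
        ps.add("phi", np.zeros(nr) if phi0 is None else phi0, scale=1.0)
        if photons0 is None:
            s0 = np.clip(self.data.sum(axis=(1, 2, 3))
                         - self.n_ch * self.roi ** 2
                         * np.median(self.data, axis=(1, 2, 3)), 10, None)
            photons0 = s0
        ps.add("photons", photons0, positive=True,
               scale=float(np.median(photons0)))
        if background0 is None:
            background0 = np.maximum(np.median(self.data, axis=(1, 2, 3)),
                                     0.01)
        ps.add("background", background0, positive=True,
               scale=float(max(np.median(background0), 0.1)))
        if self.fit_offsets:
            ps.add("channel_offset", np.zeros((self.n_ch, 2)), scale=10.0)
        return ps

    def objective_packed(self, params, theta):
        vals = params.unpack(theta)
        loss, grads = self.objective(vals)
        _check_finite(grads, loss)
        return loss, params.pack_grad(grads)

    def objective(self, vals):
        lf, lg = _data_term(self.loss_spec.data_term)
        grid = self.grid
        phi_t = np.tensordot(vals["coeffs_top"], self.zfit, axes=(0, 0))
        phi_b = np.tensordot(vals["coeffs_bottom"], self.zfit, axes=(0, 0))
        x, y, z = vals["x"], vals["y"], vals["z"]
        phi = vals["phi"]
        s, b = vals["photons"], vals["background"]
        off = vals.get("channel_offset", np.zeros((self.n_ch, 2)))
        kx2p = 2 * np.pi * grid.kx
        ky2p = 2 * np.pi * grid.ky
        kz2p = 2 * np.pi * grid.kz
        ntot = self.data.size
        loss = 0.0
        dct = np.zeros(len(self.fit_idx))
        dcb = np.zeros(len(self.fit_idx))
        gx = np.zeros(self.n_roi)
        gy = np.zeros(self.n_roi)
        gz = np.zeros(self.n_roi)
        gphi = np.zeros(self.n_roi)
        gs = np.zeros(self.n_roi)
        gb = np.zeros(self.n_roi)
        goff = np.zeros((self.n_ch, 2))
        for lo in range(0, self.n_roi, self.chunk):
            hi = min(lo + self.chunk, self.n_roi)
            nc = hi - lo
            xe = x[lo:hi, None] + off[None, :, 0]       # (nc, C)
            ye = y[lo:hi, None] + off[None, :, 1]
            lat = (kx2p[None, None] * xe[..., None, None]
                   + ky2p[None, None] * ye[..., None, None])
            defoc = kz2p[None, None] * z[lo:hi, None, None, None]
            pt = self.magnitude * np.exp(1j * (phi_t + lat + defoc))
            pb = self.magnitude * np.exp(1j * (phi_b + lat - defoc))
            et = cfft2(pt)
            eb = cfft2(pb)
            phase = np.exp(1j * (phi[lo:hi, None] + self.delta[None, :]))
            f = et + phase[..., None, None] * eb
            psf = np.abs(f) ** 2 / self.i0
            binned = pixel_integrate(psf, self.os)
            model = (binned * s[lo:hi, None, None, None]
                     + b[lo:hi, None, None, None])
            d = self.data[lo:hi]
            loss += lf(model, d) * model.size / ntot
            w = lg(model, d) * model.size / ntot
            gs[lo:hi] = np.sum(w * binned, axis=(1, 2, 3))
            gb[lo:hi] = np.sum(w, axis=(1, 2, 3))
            dpsf = np.repeat(np.repeat(w * s[lo:hi, None, None, None],
                                       self.os, axis=-2), self.os, axis=-1)
            q = dpsf / self.i0
            g = cfft2(q * np.conj(f))
            tt = g * pt
            tb = g * pb * phase[..., None, None]
            st = -2.0 * tt.imag
            sb = -2.0 * tb.imag
            both = st + sb
            gx[lo:hi] = np.einsum("ickl,kl->i", both, kx2p)
            gy[lo:hi] = np.einsum("ickl,kl->i", both, ky2p)
            gz[lo:hi] = np.einsum("ickl,kl->i", st - sb, kz2p)
            gphi[lo:hi] = sb.sum(axis=(1, 2, 3))
            if self.fit_offsets:
                goff[:, 0] += np.einsum("ickl,kl->c", both, kx2p)
                goff[:, 1] += np.einsum("ickl,kl->c", both, ky2p)
            dct += np.tensordot(st.sum(axis=(0, 1)), self.zfit,
                                axes=([-2, -1], [-2, -1]))
            dcb += np.tensordot(sb.sum(axis=(0, 1)), self.zfit,
                                axes=([-2, -1], [-2, -1]))
        grads = {"coeffs_top": dct, "coeffs_bottom": dcb, "x": gx, "y": gy,
                 "z": gz, "phi": gphi, "photons": gs, "background": gb}
        if self.fit_offsets:
            grads["channel_offset"] = goff
        return float(loss), grads

    def result_pupils(self, vals) -> tuple[ComplexPupil, ComplexPupil]:
        out = []
        for key in ("coeffs_top", "coeffs_bottom"):
            phase = np.tensordot(vals[key], self.zfit, axes=(0, 0))
            out.append(ComplexPupil(magnitude=self.magnitude,
                                    phase=np.where(self.grid.aperture, phase,
                                                   0.0),
                                    aperture=self.grid.aperture))
        return tuple(out)
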
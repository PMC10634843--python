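"""Differentiable image formation: PSF models + experimental-condition extras.

An observed ROI stack of emitter i is modelled as

    U_i = ((PSF(. - x_i) (x) g) (x) blur, pixel-integrated) * s_i + b_i

where g is the (optional) bead shape, blur an extra 2D Gaussian, s_i the
photon count (optionally per frame) and b_i the background per pixel. The
operations here implement each factor for every PSF parameterization: voxel
arrays, pupil-based models, IAB 4Pi models, multi-channel sets and
field-dependent Zernike maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .pupil import ComplexPupil, OpticalConfig, PupilGrid, cfft2, cifft2
from .psf import psf_from_fields, pupil_fields

__all__ = [
    "VoxelPSF", "EmitterParams", "BeadShape", "BlurSpec", "ShearGeometry",
    "AffineTransform2D", "IAB4PiModel", "FieldDependentModel",
    "MultiChannelPSF",
    "voxel_forward", "fourier_shift", "pupil_forward", "bead_kernel",
    "ball_transfer", "gaussian_blur", "pixel_integrate", "shear_offsets",
    "iab_evaluate", "iab_from_pupils", "fd_coeffs_at", "fd_interp_weights",
    "channel_forward",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class VoxelPSF:
    """PSF parameterized directly as a 3D intensity array (z, y, x)."""

    values: np.ndarray
    z_step: float
    pixel_size: float
    oversample: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("voxel PSF must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel PSF contains non-finite values")


@dataclass
class EmitterParams:
    """Per-emitter parameters of the forward model (positions in nm)."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    photons: float = 1.0
    background: float = 0.0
    frame_intensities: Optional[np.ndarray] = None
    drift: Optional[np.ndarray] = None  # (n_frames, 2) lateral nm

    def __post_init__(self):
        if self.photons < 0 or self.background < 0:
            raise ValueError("photons and background must be >= 0")

    def frame_photons(self, n_frames: int) -> np.ndarray:
        if self.frame_intensities is None:
            return np.full(n_frames, self.photons)
        fi = np.asarray(self.frame_intensities, float)
        if fi.shape[0] != n_frames:
            raise ValueError("frame_intensities length mismatch")
        return self.photons * fi


@dataclass
class BeadShape:
    """Normalized voxel density of a uniform fluorescent sphere."""

    diameter: float
    kernel: np.ndarray

    def __post_init__(self):
        s = self.kernel.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError("bead kernel must sum to 1")


@dataclass
class BlurSpec:
    """Extra 2D Gaussian blur, standard deviations in native pixels."""

    sigma_x: float = 0.0
    sigma_y: float = 0.0

    def __post_init__(self):
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise ValueError("blur sigmas must be >= 0")


@dataclass(frozen=True)
class ShearGeometry:
    """Stage-scan shear of a light-sheet-style bead stack.

    One stage step of ``step`` nm translates the bead by ``dx_per_step`` nm
    laterally and ``dz_per_step`` nm axially in detection coordinates; the two
    components decompose the step (dx^2 + dz^2 = step^2).
    """

    step: float
    dx_per_step: float
    dz_per_step: float

    def __post_init__(self):
        h = np.hypot(self.dx_per_step, self.dz_per_step)
        if abs(h - self.step) > 1e-6 * max(abs(self.step), 1.0):
            raise ValueError(
                f"dx^2 + dz^2 = {h:.6g}^2 does not decompose step {self.step:.6g}")

    @classmethod
    def from_lateral(cls, step: float, dx_per_step: float) -> "ShearGeometry":
        """Build from the stage step and its lateral component (axial by
        Pythagoras)."""
        dz = float(np.sqrt(step ** 2 - dx_per_step ** 2))
        return cls(step=step, dx_per_step=dx_per_step, dz_per_step=dz)


@dataclass
class AffineTransform2D:
    """2D affine map from reference-channel to target-channel coordinates."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float).reshape(2, 2)
        self.offset = np.asarray(self.offset, float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.offset)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def estimate(cls, src: np.ndarray, dst: np.ndarray) -> "AffineTransform2D":
        """Least-squares fit of the affine map sending src points to dst."""
        src = np.asarray(src, float)
        dst = np.asarray(dst, float)
        a = np.hstack([src, np.ones((len(src), 1))])
        sol, *_ = np.linalg.lstsq(a, dst, rcond=None)
        return cls(sol[:2].T, sol[2])


@dataclass
class IAB4PiModel:
    """4Pi PSF in the interference-decoupled I/A/B representation.

    Per channel c, the PSF at axial position z and interference phase
    phi = 2 pi k z + phi0 is

        U_c(x, y, z, phi) = I_c + A_c cos(phi) + B_c sin(phi)

    with the channel's fixed interferometric phase offset folded into
    (A_c, B_c). Arrays have shape (n_channels, nz, ny, nx).
    """

    I: np.ndarray
    A: np.ndarray
    B: np.ndarray
    k: float            # interference wave number, cycles/nm
    phi0: float = 0.0
    z_step: float = 50.0
    channel_phases: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("I", "A", "B"):
            arr = np.asarray(getattr(self, name), float)
            if arr.ndim == 3:
                arr = arr[None]
            setattr(self, name, arr)
        if not (self.I.shape == self.A.shape == self.B.shape):
            raise ValueError("I, A, B must share one shape")

    @property
    def n_channels(self) -> int:
        return self.I.shape[0]

    def z_axis(self) -> np.ndarray:
        nz = self.I.shape[1]
        return (np.arange(nz) - nz // 2) * self.z_step


@dataclass
class FieldDependentModel:
    """Per-Zernike-mode coefficient maps across the field of view.

    ``maps`` has shape (n_modes, my, mx); each map pixel holds the coefficient
    at the center of a ``map_pitch`` x ``map_pitch`` (pixel) subregion of the
    FOV. Queries between centers are bilinearly interpolated; outside, edge
    values are clamped.
    """

    maps: np.ndarray
    map_pitch: float
    modes: Sequence[tuple[int, int]]
    blur: Optional[BlurSpec] = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, float)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (n_modes, my, mx)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("maps contain non-finite values")


@dataclass
class MultiChannelPSF:
    """Per-channel PSF renderers + affine transforms + photon fractions."""

    renderers: Sequence[Callable[[float, float, float], np.ndarray]]
    transforms: Sequence[AffineTransform2D]
    fractions: Optional[np.ndarray] = None
    pixel_size: float = 100.0

    def __post_init__(self):
        if len(self.renderers) != len(self.transforms):
            raise ValueError("one transform per channel required")
        if self.fractions is None:
            self.fractions = np.full(len(self.renderers),
                                     1.0 / len(self.renderers))


# ---------------------------------------------------------------------------
# Fourier shift machinery


def _freqs(n: int) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftfreq(n))


def fourier_shift(vol: np.ndarray, shift_vox: Sequence[float]) -> np.ndarray:
    """Shift an array by sub-voxel amounts via Fourier phase ramps.

    ``shift_vox`` gives the shift in voxels per trailing axis; positive values
    move content toward increasing indices. Content wraps around circularly,
    so callers must keep shifts inside a guard band.
    """
    vol = np.asarray(vol, float)
    nd = len(shift_vox)
    axes = tuple(range(vol.ndim - nd, vol.ndim))
    f = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol, axes=axes), axes=axes),
                        axes=axes)
    for ax, s in zip(axes, shift_vox):
        n = vol.shape[ax]
        shape = [1] * vol.ndim
        shape[ax] = n
        f = f * np.exp(-2j * np.pi * _freqs(n) * s).reshape(shape)
    out = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(f, axes=axes), axes=axes),
                          axes=axes)
    return out.real


def voxel_forward(psf: VoxelPSF, emitter: EmitterParams,
                  n_frames: int | None = None) -> np.ndarray:
    """Render a voxel-PSF model stack for one emitter.

    The PSF array is shifted to the emitter position by Fourier phase ramps
    (sub-pixel exact up to wraparound), scaled by the per-frame photon count
    and offset by the background.
    """
    nz, ny, nx = psf.values.shape
    if n_frames is None:
        n_frames = nz
    dy = emitter.y / (psf.pixel_size / psf.oversample)
    dx = emitter.x / (psf.pixel_size / psf.oversample)
    dz = emitter.z / psf.z_step
    if abs(dx) > nx / 4 or abs(dy) > ny / 4:
        raise ValueError("lateral shift beyond wraparound guard band (N/4)")
    shifted = fourier_shift(psf.values, (dz, dy, dx))
    if emitter.drift is not None:
        drift = np.asarray(emitter.drift, float)
        out = np.empty_like(shifted)
        for j in range(nz):
            ddx = drift[j, 0] / (psf.pixel_size / psf.oversample)
            ddy = drift[j, 1] / (psf.pixel_size / psf.oversample)
            out[j] = fourier_shift(shifted[j], (ddy, ddx))
        shifted = out
    s = emitter.frame_photons(n_frames)[:, None, None]
    return shifted * s + emitter.background


# ---------------------------------------------------------------------------
# Bead, blur, pixelation


def bead_kernel(diameter: float, pitches: Sequence[float],
                shape: Sequence[int] | None = None,
                subsample: int = 3) -> BeadShape:
    """Voxelize a uniform sphere of the given diameter, unit sum.

    ``pitches`` is (dz, dy, dx) in nm. Voxel occupancy is estimated by
    averaging an inside-sphere indicator over ``subsample``^3 points per
    voxel, which keeps the volume accurate for spheres only a few voxels
    across. Diameter 0 yields the delta kernel.
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    pitches = np.asarray(pitches, float)
    if shape is None:
        half = np.ceil(diameter / 2 / pitches).astype(int) + 1
        shape = tuple(2 * half + 1)
    shape = tuple(int(s) for s in shape)
    if diameter == 0:
        k = np.zeros(shape)
        k[shape[0] // 2, shape[1] // 2, shape[2] // 2] = 1.0
        return BeadShape(diameter=0.0, kernel=k)
    r = diameter / 2
    for s, p in zip(shape, pitches):
        if diameter > s * p:
            raise ValueError("bead diameter exceeds the kernel grid extent")
    axes = []
    for n, p in zip(shape, pitches):
        sub = (np.arange(subsample) + 0.5) / subsample - 0.5
        centers = (np.arange(n) - n // 2)[:, None] + sub[None, :]
        axes.append((centers * p).ravel())
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    inside = (zz ** 2 + yy ** 2 + xx ** 2) <= r ** 2
    k = inside.reshape(shape[0], subsample, shape[1], subsample,
                       shape[2], subsample).mean(axis=(1, 3, 5)).astype(float)
    total = k.sum()
    if total <= 0:
        # sphere smaller than one voxel: all mass in the central voxel
        k = np.zeros(shape)
        k[shape[0] // 2, shape[1] // 2, shape[2] // 2] = 1.0
        return BeadShape(diameter=diameter, kernel=k)
    return BeadShape(diameter=diameter, kernel=k / total)


def ball_transfer(diameter: float, kz: np.ndarray, ky: np.ndarray,
                  kx: np.ndarray) -> np.ndarray:
    """3D Fourier transform of the normalized uniform ball (analytic).

    Evaluated at frequency samples (cycles/nm); equals 1 at zero frequency.
    Using the analytic transform avoids voxelization error for beads not
    much larger than a voxel.
    """
    if diameter == 0:
        return np.ones(np.broadcast_shapes(kz.shape, ky.shape, kx.shape))
    r = diameter / 2
    q = 2 * np.pi * r * np.sqrt(kz ** 2 + ky ** 2 + kx ** 2)
    out = np.ones_like(q)
    nz = q > 1e-6
    qq = q[nz]
    out[nz] = 3 * (np.sin(qq) - qq * np.cos(qq)) / qq ** 3
    return out


def bead_blur_stack(stack: np.ndarray, diameter: float, z_step: float,
                    sample_spacing: float) -> np.ndarray:
    """Convolve a PSF z-stack with the uniform-ball kernel in 3D Fourier space.

    Circular in all three axes; the stack must carry enough axial padding
    that wraparound is negligible for the bead sizes in use.
    """
    if diameter == 0:
        return stack
    nz, ny, nx = stack.shape[-3:]
    kz = np.fft.fftfreq(nz, d=z_step)[:, None, None]
    ky = np.fft.fftfreq(ny, d=sample_spacing)[None, :, None]
    kx = np.fft.fftfreq(nx, d=sample_spacing)[None, None, :]
    g = ball_transfer(diameter, kz, ky, kx)
    f = np.fft.fftn(stack, axes=(-3, -2, -1))
    return np.fft.ifftn(f * g, axes=(-3, -2, -1)).real


def gaussian_blur(images: np.ndarray, blur: BlurSpec,
                  sample_spacing: float, pixel_size: float) -> np.ndarray:
    """Extra 2D Gaussian blur applied in frequency space (last two axes).

    Sigmas are specified in native camera pixels; ``sample_spacing`` is the
    (possibly oversampled) grid spacing in nm.
    """
    if blur.sigma_x == 0 and blur.sigma_y == 0:
        return images
    ny, nx = images.shape[-2:]
    ky = np.fft.fftfreq(ny, d=sample_spacing)[:, None]
    kx = np.fft.fftfreq(nx, d=sample_spacing)[None, :]
    sx = blur.sigma_x * pixel_size
    sy = blur.sigma_y * pixel_size
    g = np.exp(-2 * np.pi ** 2 * ((sx * kx) ** 2 + (sy * ky) ** 2))
    f = np.fft.fft2(images, axes=(-2, -1))
    return np.fft.ifft2(f * g, axes=(-2, -1)).real


def pixel_integrate(image: np.ndarray, factor: int) -> np.ndarray:
    """Bin an oversampled image by summing factor x factor blocks."""
    if factor == 1:
        return image
    *lead, ny, nx = image.shape
    if ny % factor or nx % factor:
        raise ValueError(f"image shape {(ny, nx)} not divisible by {factor}")
    return image.reshape(*lead, ny // factor, factor, nx // factor, factor
                         ).sum(axis=(-3, -1))


def shear_offsets(geometry: ShearGeometry, n_slices: int
                  ) -> list[tuple[float, float]]:
    """Cumulative (dx, dz) displacement of each stack slice, nm.

    Slice j of a stage-scanned stack is laterally displaced by
    j * dx_per_step while its axial coordinate advances by j * dz_per_step;
    the integer-pixel part of dx is removed in preprocessing (deskew) and the
    fractional part belongs in the forward model.
    """
    return [(j * geometry.dx_per_step, j * geometry.dz_per_step)
            for j in range(n_slices)]


# ---------------------------------------------------------------------------
# Pupil-based forward model


def pupil_forward(pupil: ComplexPupil, grid: PupilGrid,
                  emitter: EmitterParams,
                  z_slices: np.ndarray | None = None,
                  field_factors_: np.ndarray | None = None,
                  bead_diameter: float = 0.0,
                  blur: BlurSpec | None = None,
                  depth_amplitude: np.ndarray | None = None,
                  shear: ShearGeometry | None = None) -> np.ndarray:
    """Render a (stack of) camera-sampled model image(s) from a pupil model.

    Chains diffraction PSF -> bead convolution -> extra blur -> pixel
    integration -> photons/background, all in photons. ``z_slices`` gives the
    stage z of each frame (nm); a single in-focus frame is rendered when
    omitted.
    """
    cfg = grid.config
    if z_slices is None:
        z_slices = np.array([0.0])
    z_slices = np.asarray(z_slices, float)
    if field_factors_ is None:
        field_factors_ = pupil.field()[None]
        base = field_factors_
    else:
        base = pupil_fields(pupil, field_factors_)
    if depth_amplitude is not None:
        base = base * depth_amplitude
    i0 = grid.grid_size ** 2 * np.sum(np.abs(base) ** 2)
    stack = []
    for j, zs in enumerate(z_slices):
        x, y = emitter.x, emitter.y
        if shear is not None:
            x = x + j * shear.dx_per_step
        if emitter.drift is not None:
            x = x + emitter.drift[j, 0]
            y = y + emitter.drift[j, 1]
        stack.append(psf_from_fields(base, grid, (x, y, emitter.z + zs),
                                     normalization=i0))
    psf_stack = np.stack(stack)
    if bead_diameter:
        psf_stack = bead_blur_stack(psf_stack, bead_diameter, cfg.z_step,
                                    grid.sample_spacing)
    if blur is not None:
        psf_stack = gaussian_blur(psf_stack, blur, grid.sample_spacing,
                                  cfg.pixel_size_xy)
    binned = pixel_integrate(psf_stack, cfg.oversample)
    s = emitter.frame_photons(len(z_slices))[:, None, None]
    return binned * s + emitter.background


# ---------------------------------------------------------------------------
# IAB 4Pi model


def iab_from_pupils(pupil_top: ComplexPupil, pupil_bottom: ComplexPupil,
                    grid: PupilGrid, config: OpticalConfig | None = None,
                    phi0: float = 0.0,
                    z_slices: np.ndarray | None = None,
                    channel_phases: Sequence[float] | None = None,
                    normalize: bool = True) -> IAB4PiModel:
    """Synthesize an IAB model by coherently adding the two objective arms.

    Per z-slice, with arm fields E_t (top, defocus +z) and E_b (bottom,
    defocus -z) and M = conj(E_t) * E_b:

        I   = |E_t|^2 + |E_b|^2
        A_c = 2 Re(M e^{i d_c}),  B_c = -2 Im(M e^{i d_c})

    so that U_c(phi) = I + A_c cos(phi) + B_c sin(phi) equals
    |E_t + e^{i(phi + d_c)} E_b|^2 for every phase.
    """
    cfg = config or grid.config
    if z_slices is None:
        nz = 2 * int(600 / cfg.z_step) + 1
        z_slices = (np.arange(nz) - nz // 2) * cfg.z_step
    z_slices = np.asarray(z_slices, float)
    if channel_phases is None:
        channel_phases = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
    pt = pupil_top.field()
    pb = pupil_bottom.field()
    n2 = grid.grid_size ** 2
    i0 = n2 * (np.sum(np.abs(pt) ** 2) + np.sum(np.abs(pb) ** 2))
    if not normalize or i0 == 0:
        i0 = 1.0
    i_list, m_list = [], []
    for zs in z_slices:
        et = cfft2(pt * np.exp(2j * np.pi * grid.kz * zs))
        eb = cfft2(pb * np.exp(-2j * np.pi * grid.kz * zs))
        i_list.append((np.abs(et) ** 2 + np.abs(eb) ** 2) / i0)
        m_list.append(np.conj(et) * eb / i0)
    i_arr = np.stack(i_list)
    m_arr = np.stack(m_list)
    chans_i, chans_a, chans_b = [], [], []
    for d in channel_phases:
        me = m_arr * np.exp(1j * d)
        chans_i.append(i_arr)
        chans_a.append(2 * me.real)
        chans_b.append(-2 * me.imag)
    return IAB4PiModel(I=np.stack(chans_i), A=np.stack(chans_a),
                       B=np.stack(chans_b), k=cfg.k_immersion, phi0=phi0,
                       z_step=float(z_slices[1] - z_slices[0])
                       if len(z_slices) > 1 else cfg.z_step,
                       channel_phases=np.asarray(channel_phases, float))


def iab_evaluate(model: IAB4PiModel, z: float, phi: float,
                 lateral_shift: tuple[float, float] = (0.0, 0.0),
                 pixel_size: float | None = None) -> np.ndarray:
    """Evaluate the per-channel 4Pi PSF at axial position z and phase phi.

    z interpolates the I/A/B envelopes linearly between stored slices (error
    outside the sampled range); phi enters only through cos/sin, so the
    output is exactly 2-pi periodic. ``lateral_shift`` is (dx, dy) in pixels
    unless ``pixel_size`` is given (then nm).
    """
    zax = model.z_axis()
    if z < zax[0] - 1e-9 or z > zax[-1] + 1e-9:
        raise ValueError(f"z={z} outside sampled range [{zax[0]}, {zax[-1]}]")
    t = np.clip((z - zax[0]) / model.z_step, 0, len(zax) - 1)
    j0 = int(np.floor(min(t, len(zax) - 2)))
    w = t - j0

    def interp(arr):
        return (1 - w) * arr[:, j0] + w * arr[:, j0 + 1]

    i_sl, a_sl, b_sl = interp(model.I), interp(model.A), interp(model.B)
    out = i_sl + a_sl * np.cos(phi) + b_sl * np.sin(phi)
    dx, dy = lateral_shift
    if pixel_size:
        dx, dy = dx / pixel_size, dy / pixel_size
    if dx or dy:
        out = np.stack([fourier_shift(ch, (dy, dx)) for ch in out])
    return out


# ---------------------------------------------------------------------------
# Field-dependent maps


def fd_interp_weights(model: FieldDependentModel, fov_xy: Sequence[float]
                      ) -> list[tuple[int, int, float]]:
    """Bilinear interpolation stencil (iy, ix, weight) for a FOV position.

    Map nodes sit at subregion centers ((n + 0.5) * pitch - 0.5 in pixel
    coordinates); queries outside are clamped to the edge nodes.
    """
    _, my, mx = model.maps.shape
    x, y = fov_xy
    # node n sits at pixel coordinate (n + 0.5) * pitch - 0.5 (pixel centers
    # at integers, subregion n covering pixels [n*pitch, (n+1)*pitch))
    u = np.clip((x + 0.5) / model.map_pitch - 0.5, 0.0, mx - 1.0)
    v = np.clip((y + 0.5) / model.map_pitch - 0.5, 0.0, my - 1.0)
    ix0 = int(np.floor(min(u, mx - 2))) if mx > 1 else 0
    iy0 = int(np.floor(min(v, my - 2))) if my > 1 else 0
    fu = u - ix0 if mx > 1 else 0.0
    fv = v - iy0 if my > 1 else 0.0
    out = []
    for (iy, wv) in (((iy0, 1 - fv),) if my == 1 else
                     ((iy0, 1 - fv), (iy0 + 1, fv))):
        for (ix, wu) in (((ix0, 1 - fu),) if mx == 1 else
                         ((ix0, 1 - fu), (ix0 + 1, fu))):
            out.append((iy, ix, wv * wu))
    return out


def fd_coeffs_at(model: FieldDependentModel, fov_xy: Sequence[float]
                 ) -> np.ndarray:
    """Zernike coefficient vector at a FOV position (bilinear, edge-clamped)."""
    w = fd_interp_weights(model, fov_xy)
    out = np.zeros(model.maps.shape[0])
    for iy, ix, wt in w:
        out += wt * model.maps[:, iy, ix]
    return out


# ---------------------------------------------------------------------------
# Multi-channel forward


def channel_forward(mc: MultiChannelPSF, emitter: EmitterParams
                    ) -> list[np.ndarray]:
    """Render each channel's model image for an emitter in reference coords.

    The emitter's lateral position (nm) is converted to reference-channel
    pixels, mapped through each channel's affine transform, and rendered with
    that channel's PSF; photons are split by the per-channel fractions.
    """
    ref_px = np.array([emitter.x, emitter.y]) / mc.pixel_size
    out = []
    for rend, tr, frac in zip(mc.renderers, mc.transforms, mc.fractions):
        tgt_px = tr.apply(ref_px)[0]
        x_nm, y_nm = tgt_px * mc.pixel_size
        img = rend(x_nm, y_nm, emitter.z)
        out.append(img * emitter.photons * frac + emitter.background)
    return out
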
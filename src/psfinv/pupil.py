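"""Pupil-plane optics: frequency grids, complex pupils, apodization, depth.

The pupil function ``h(kx, ky) = A(kx, ky) * exp(i * Phi(kx, ky))`` is the
complex field at the objective back focal plane; it fully parameterizes the
PSF in the Fourier domain. Frequency coordinates are in cycles/nm, with the
circular aperture cutoff at NA/lambda and the wave-vector magnitude
k = n/lambda set by the immersion index.

Layout convention: all 2D arrays are row-major (y, x); the zero-frequency
sample sits at index ``floor(N/2)`` on both axes (centered grids), and the
matching centered transforms are :func:`cfft2` / :func:`cifft2`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .zernike import ZernikeBasis

__all__ = [
    "OpticalConfig",
    "PupilGrid",
    "ComplexPupil",
    "build_pupil_grid",
    "cfft2",
    "cifft2",
    "apodization",
    "depth_phase",
    "effective_na",
    "strehl_ratio",
]


def cfft2(a: np.ndarray) -> np.ndarray:
    """Centered 2D FFT over the last two axes (zero frequency at floor(N/2))."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a, axes=(-2, -1))),
                           axes=(-2, -1))


def cifft2(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cfft2`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a, axes=(-2, -1))),
                           axes=(-2, -1))


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and sampling parameters of the imaging system.

    Parameters
    ----------
    na : float
        Numerical aperture of the objective (dimensionless, > 0 and
        <= n_immersion).
    wavelength : float
        Emission wavelength lambda in nm.
    n_immersion : float
        Refractive index of the immersion medium.
    n_medium : float
        Refractive index of the sample medium (defaults to the immersion
        index, i.e. matched).
    pixel_size_xy : float
        Camera pixel size projected into sample space, nm.
    z_step : float
        Axial spacing of stack slices, nm.
    roi_size : int
        ROI edge length in (native) pixels.
    oversample : int
        Integer oversampling factor >= 1 used when rendering PSFs before
        pixel binning.
    """

    na: float = 1.35
    wavelength: float = 660.0
    n_immersion: float = 1.406
    n_medium: Optional[float] = None
    pixel_size_xy: float = 120.0
    z_step: float = 50.0
    roi_size: int = 21
    oversample: int = 2

    def __post_init__(self):
        if self.n_medium is None:
            object.__setattr__(self, "n_medium", self.n_immersion)
        if not self.na > 0:
            raise ValueError("na must be > 0")
        if self.na > self.n_immersion + 1e-12:
            raise ValueError("na must not exceed n_immersion")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be > 0")
        if not self.pixel_size_xy > 0:
            raise ValueError("pixel_size_xy must be > 0")
        if int(self.oversample) != self.oversample or self.oversample < 1:
            raise ValueError("oversample must be an integer >= 1")

    @property
    def cutoff(self) -> float:
        """Aperture cutoff frequency NA/lambda, cycles/nm."""
        return self.na / self.wavelength

    @property
    def k_immersion(self) -> float:
        """Wave-vector magnitude n_immersion/lambda, cycles/nm."""
        return self.n_immersion / self.wavelength

    @property
    def k_medium(self) -> float:
        return self.n_medium / self.wavelength


@dataclass
class PupilGrid:
    """Cartesian frequency grids supporting a circular pupil.

    ``kz`` is sqrt(k^2 - kx^2 - ky^2) with k = n_immersion/lambda where the
    argument is non-negative and 0 outside; ``aperture`` is the binary support
    mask of the NA/lambda disk.
    """

    config: OpticalConfig
    grid_size: int
    kx: np.ndarray = field(repr=False)
    ky: np.ndarray = field(repr=False)
    kr: np.ndarray = field(repr=False)
    kz: np.ndarray = field(repr=False)
    aperture: np.ndarray = field(repr=False)

    @property
    def k(self) -> float:
        return self.config.k_immersion

    @property
    def sample_spacing(self) -> float:
        """Real-space sampling of the conjugate image grid, nm."""
        return self.config.pixel_size_xy / self.config.oversample

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(rho, theta) with rho scaled so the aperture rim is 1."""
        rho = self.kr / self.config.cutoff
        theta = np.arctan2(self.ky, self.kx)
        return rho, theta

    def zernike_basis(self, modes=None, max_radial_order: int = 8,
                      scheme: str = "noll") -> ZernikeBasis:
        rho, theta = self.polar()
        return ZernikeBasis.from_grid(rho, theta, modes=modes,
                                      max_radial_order=max_radial_order,
                                      scheme=scheme)


def build_pupil_grid(config: OpticalConfig,
                     grid_size: int | None = None) -> PupilGrid:
    """Build the centered frequency grid for a given optical configuration.

    The grid spans the conjugate of an image patch of ``grid_size`` samples at
    spacing ``pixel_size_xy / oversample``; the Nyquist extent must contain
    the aperture cutoff NA/lambda, otherwise the sampling is too coarse and a
    ValueError is raised.
    """
    if grid_size is None:
        grid_size = config.roi_size * config.oversample
    if grid_size < 4:
        raise ValueError("grid_size must be >= 4")
    dx = config.pixel_size_xy / config.oversample
    f = np.fft.fftshift(np.fft.fftfreq(grid_size, d=dx))
    kx, ky = np.meshgrid(f, f)  # row-major: ky varies along axis 0? meshgrid default: kx along axis1
    # meshgrid(f, f) returns (X, Y) with X varying along axis 1 (x) and Y along
    # axis 0 (y), matching the (y, x) array layout.
    kr = np.hypot(kx, ky)
    if f.max() < config.cutoff:
        raise ValueError(
            f"grid too coarse: Nyquist {f.max():.3e} cycles/nm < cutoff "
            f"{config.cutoff:.3e}; decrease pixel size or increase oversample")
    k = config.k_immersion
    kz2 = k ** 2 - kr ** 2
    kz = np.sqrt(np.clip(kz2, 0.0, None))
    aperture = kr <= config.cutoff
    return PupilGrid(config=config, grid_size=grid_size,
                     kx=kx, ky=ky, kr=kr, kz=kz, aperture=aperture)


@dataclass
class ComplexPupil:
    """Pupil magnitude/phase fields, optionally Zernike-parameterized.

    ``magnitude_mode`` records how the magnitude is represented: one of
    ``"free-image"``, ``"zernike"``, ``"rotationally-symmetric"``,
    ``"constant"``.
    """

    magnitude: np.ndarray = field(repr=False)
    phase: np.ndarray = field(repr=False)
    coeff_magnitude: Optional[np.ndarray] = None
    coeff_phase: Optional[np.ndarray] = None
    magnitude_mode: str = "constant"
    aperture: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude/phase shape mismatch")
        if np.any(self.magnitude < -1e-12):
            raise ValueError("pupil magnitude must be non-negative")
        if self.aperture is not None:
            out = ~self.aperture
            self.magnitude = np.where(out, 0.0, self.magnitude)
            self.phase = np.where(out, 0.0, self.phase)

    @classmethod
    def from_zernike(cls, grid: PupilGrid, basis: ZernikeBasis,
                     coeff_phase: np.ndarray,
                     coeff_magnitude: Optional[np.ndarray] = None
                     ) -> "ComplexPupil":
        """Pupil with Zernike phase (and optionally magnitude) expansions."""
        coeff_phase = np.asarray(coeff_phase, dtype=float)
        phase = basis.compose(coeff_phase)
        if coeff_magnitude is None:
            mag = np.where(grid.aperture, 1.0, 0.0)
            mode = "constant"
        else:
            mag = np.clip(basis.compose(coeff_magnitude), 0.0, None)
            mode = "zernike"
        return cls(magnitude=np.where(grid.aperture, mag, 0.0),
                   phase=np.where(grid.aperture, phase, 0.0),
                   coeff_magnitude=(None if coeff_magnitude is None
                                    else np.asarray(coeff_magnitude, float)),
                   coeff_phase=coeff_phase, magnitude_mode=mode,
                   aperture=grid.aperture)

    def field(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


def apodization(grid: PupilGrid, config: OpticalConfig | None = None,
                index_matched: bool = True) -> np.ndarray:
    """Angle-dependent pupil amplitude factor from energy conservation.

    With the Abbe sine condition, equal-energy annuli on the emission sphere
    map to annuli of the back focal plane compressed by cos(theta); conserving
    flux requires a field amplitude factor 1/sqrt(cos theta) with
    sin(theta) = k_transverse / k_immersion (index-matched case).

    For a mismatched medium the interface transmission redistributes energy;
    the factor used is sqrt(cos theta_med) / cos theta_imm so a uniformly
    emitting source produces a near-uniform retrieved pupil magnitude.

    cos(theta) is clamped at 1e-3 before inversion to keep rim samples finite.
    """
    cfg = config or grid.config
    sin_i = np.clip(grid.kr / cfg.k_immersion, 0.0, 1.0)
    cos_i = np.sqrt(np.clip(1.0 - sin_i ** 2, 0.0, None))
    cos_i = np.maximum(cos_i, 1e-3)
    if index_matched:
        out = 1.0 / np.sqrt(cos_i)
    else:
        sin_m2 = (grid.kr / cfg.k_medium) ** 2
        cos_m = np.sqrt(np.clip(1.0 - sin_m2, 0.0, None))
        out = np.sqrt(np.maximum(cos_m, 1e-3)) / cos_i
    return np.where(grid.aperture, out, 0.0)


def depth_phase(depth: float, grid: PupilGrid,
                config: OpticalConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Depth-induced aberration phase for an emitter above the coverslip.

    For an emitter at ``depth`` nm in a medium of index n_medium imaged
    through immersion of index n_immersion, the pupil acquires the phase
    ``2*pi*depth*(kz_medium - kz_immersion)`` where kz_medium is computed with
    k = n_medium/lambda. Transverse frequencies beyond n_medium/lambda are
    evanescent in the medium (supercritical-angle emission): at depth 0 they
    carry energy, at depth d their amplitude decays as
    ``exp(-2*pi*|Im kz_medium|*d)``.

    Returns
    -------
    phase : ndarray
        Added pupil phase in radians (zero on the evanescent samples).
    amplitude : ndarray
        Multiplicative amplitude factor (1 on propagating samples, the
        evanescent decay elsewhere inside the aperture).
    propagating : ndarray of bool
        Mask of samples that propagate in the medium; its cutoff radius is
        min(NA, n_medium)/lambda.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    cfg = config or grid.config
    kz_imm = grid.kz
    kz_med2 = cfg.k_medium ** 2 - grid.kr ** 2
    propagating = (kz_med2 > 0) & grid.aperture
    kz_med = np.sqrt(np.clip(kz_med2, 0.0, None))
    kz_med_imag = np.sqrt(np.clip(-kz_med2, 0.0, None))
    phase = np.where(propagating, 2 * np.pi * depth * (kz_med - kz_imm), 0.0)
    amplitude = np.where(propagating, 1.0,
                         np.exp(-2 * np.pi * kz_med_imag * depth))
    amplitude = np.where(grid.aperture, amplitude, 0.0)
    return phase, amplitude, propagating


def effective_na(config: OpticalConfig, depth: float = np.inf,
                 tol: float = 1e-12) -> float:
    """Effective NA of the depth-dependent pupil.

    At large depth the evanescent (supercritical-angle) band no longer
    contributes, so the propagating support shrinks to
    min(NA, n_medium)/lambda. The cutoff radius is located by bisection on
    the continuous propagating-support indicator and converted back to an NA.
    At depth 0 the full aperture contributes and the effective NA is the
    nominal one.
    """
    if depth == 0:
        return config.na

    def propagates(kr: float) -> bool:
        return (kr <= config.cutoff + tol
                and config.k_medium ** 2 - kr ** 2 > -tol)

    lo, hi = 0.0, config.k_immersion
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if propagates(mid):
            lo = mid
        else:
            hi = mid
    return lo * config.wavelength


def strehl_ratio(pupil: ComplexPupil) -> float:
    """Aberrated / unaberrated on-axis peak intensity ratio.

    Computed over the pupil support as |sum A e^{i Phi}|^2 / (sum A)^2, which
    is 1 for any constant phase and decreases with aberration strength
    (approximately exp(-sigma^2) for small RMS phase sigma).
    """
    a = pupil.magnitude
    denom = a.sum()
    if denom <= 0:
        raise ValueError("pupil has zero energy")
    num = np.abs(np.sum(a * np.exp(1j * pupil.phase))) ** 2
    return float(num / denom ** 2)
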
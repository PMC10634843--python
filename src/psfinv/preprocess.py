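"""Camera-to-photon conversion, emitter detection, ROI cropping, deskewing.

Coordinates are 0-based with pixel centers at integer positions; the FOV
origin is array index (0, 0). ROIs are cut so that the candidate center lands
on the ROI's center pixel ``floor(roi_size/2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .forward import ShearGeometry

log = logging.getLogger(__name__)

__all__ = [
    "CameraCalibration", "ROIDataset", "to_photons", "detect_beads",
    "crop_rois", "detect_blinking_candidates", "deskew_integer",
    "read_tiff", "write_tiff",
]


@dataclass(frozen=True)
class CameraCalibration:
    """Affine camera calibration: photons = (ADU - offset) / gain.

    ``em_excess_noise`` marks EM-multiplied cameras whose multiplicative
    register doubles the variance; those counts are halved before Poisson
    modelling (variance-doubling approximation).
    """

    offset: float = 100.0
    gain: float = 2.0
    em_excess_noise: bool = False

    def __post_init__(self):
        if not self.gain > 0:
            raise ValueError("gain must be > 0")


def to_photons(raw: np.ndarray, cal: CameraCalibration
               ) -> tuple[np.ndarray, int]:
    """Convert raw camera counts to photons; clamp negatives to zero.

    Returns the photon frames and the number of clamped pixels.
    """
    phot = (np.asarray(raw, float) - cal.offset) / cal.gain
    if cal.em_excess_noise:
        phot = phot / 2.0
    n_clamped = int(np.sum(phot < 0))
    return np.clip(phot, 0.0, None), n_clamped


@dataclass
class ROIDataset:
    """Stacked image regions (in photons) with per-ROI metadata.

    ``rois`` has shape (n_roi, n_frames, R, R); bead stacks keep all slices,
    blinking emitters have n_frames = 1. ``roi_origin`` holds the (row, col)
    FOV index of each ROI's [0, 0] corner, so FOV coordinates are exactly
    recoverable.
    """

    rois: np.ndarray
    roi_origin: np.ndarray
    kind: str = "bead-stack"          # "bead-stack" | "blinking-emitter"
    frame_index: Optional[np.ndarray] = None
    channel: Optional[np.ndarray] = None
    stage_z: Optional[np.ndarray] = None

    def __post_init__(self):
        self.rois = np.asarray(self.rois, float)
        if self.rois.ndim == 3:
            self.rois = self.rois[:, None]
        if not np.all(np.isfinite(self.rois)):
            raise ValueError("ROI data contains non-finite values")
        self.roi_origin = np.asarray(self.roi_origin, int).reshape(-1, 2)

    @property
    def n_roi(self) -> int:
        return self.rois.shape[0]

    @property
    def roi_size(self) -> int:
        return self.rois.shape[-1]

    def fov_centers(self) -> np.ndarray:
        """(x, y) FOV pixel coordinates of each ROI's center pixel."""
        half = self.roi_size // 2
        return self.roi_origin[:, ::-1] + half


def _smooth_detect(frame: np.ndarray, sigma_lo: float = 1.0,
                   sigma_hi: float = 2.5) -> np.ndarray:
    """Difference-of-Gaussians band-pass used for spot candidate detection."""
    return (ndimage.gaussian_filter(frame, sigma_lo)
            - ndimage.gaussian_filter(frame, sigma_hi))


def _local_maxima(img: np.ndarray, threshold: float, min_separation: float
                  ) -> np.ndarray:
    size = max(3, int(2 * np.floor(min_separation / 2) + 1))
    mx = ndimage.maximum_filter(img, size=size, mode="nearest")
    cand = np.argwhere((img >= mx) & (img > threshold))
    if len(cand) < 2:
        return cand
    # pairwise min-separation: reject *both* members of close pairs
    d2 = np.sum((cand[:, None] - cand[None, :]) ** 2, axis=-1).astype(float)
    np.fill_diagonal(d2, np.inf)
    keep = d2.min(axis=1) >= min_separation ** 2
    n_rej = int(np.sum(~keep))
    if n_rej:
        log.info("rejected %d candidates closer than %g px", n_rej,
                 min_separation)
    return cand[keep]


def detect_beads(stack: np.ndarray, min_separation: float = 10.0,
                 intensity_threshold: float = 10.0,
                 roi_size: int = 21) -> np.ndarray:
    """Detect bead centers on the central-slice projection of a z-stack.

    Local maxima of a difference-of-Gaussians-smoothed projection above
    ``intensity_threshold`` (photons), non-maximum suppressed; candidates
    nearer than roi_size/2 to an edge or than ``min_separation`` to each
    other are rejected. Returns (row, col) integer centers.
    """
    stack = np.atleast_3d(np.asarray(stack, float))
    if stack.ndim == 2:
        stack = stack[None]
    nz = stack.shape[0]
    proj = stack[max(0, nz // 2 - 2):nz // 2 + 3].mean(axis=0)
    det = _smooth_detect(proj)
    cand = _local_maxima(det, intensity_threshold, min_separation)
    half = roi_size // 2
    ny, nx = proj.shape
    ok = ((cand[:, 0] >= half) & (cand[:, 0] < ny - half)
          & (cand[:, 1] >= half) & (cand[:, 1] < nx - half))
    if np.sum(~ok):
        log.info("rejected %d candidates too close to the FOV edge",
                 int(np.sum(~ok)))
    out = cand[ok]
    if len(out) == 0:
        log.warning("no bead candidates found")
    return out


def crop_rois(frames: np.ndarray, centers: np.ndarray, roi_size: int,
              kind: str = "bead-stack",
              stage_z: np.ndarray | None = None) -> ROIDataset:
    """Crop integer-aligned ROIs around candidate centers.

    The center lands on ROI pixel floor(roi_size/2); out-of-bounds centers
    are skipped with a log message. Re-cropping from the recorded origins
    reproduces identical pixels.
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    half = roi_size // 2
    ny, nx = frames.shape[-2:]
    rois, origins = [], []
    for (r, c) in np.asarray(centers, int):
        r0, c0 = r - half, c - half
        if r0 < 0 or c0 < 0 or r0 + roi_size > ny or c0 + roi_size > nx:
            log.info("skipping out-of-bounds center (%d, %d)", r, c)
            continue
        rois.append(frames[:, r0:r0 + roi_size, c0:c0 + roi_size])
        origins.append((r0, c0))
    if not rois:
        return ROIDataset(rois=np.zeros((0, frames.shape[0], roi_size,
                                         roi_size)),
                          roi_origin=np.zeros((0, 2), int), kind=kind,
                          stage_z=stage_z)
    return ROIDataset(rois=np.stack(rois), roi_origin=np.array(origins),
                      kind=kind, stage_z=stage_z)


def detect_blinking_candidates(movie: np.ndarray, threshold: float = 20.0,
                               roi_size: int = 21,
                               min_separation: float | None = None,
                               max_per_frame: int = 50,
                               sigma_lo: float = 1.0,
                               sigma_hi: float = 2.5) -> ROIDataset:
    """Per-frame single-molecule candidate detection for in situ modelling.

    Spots are detected frame by frame as for beads; overlapping candidates
    within a frame (closer than ``min_separation``, default roi_size/2) are
    both rejected so every kept ROI contains a single emitter. The per-ROI
    frame index and FOV origin are retained.
    """
    movie = np.asarray(movie, float)
    if movie.ndim == 2:
        movie = movie[None]
    if min_separation is None:
        min_separation = roi_size / 2
    half = roi_size // 2
    ny, nx = movie.shape[-2:]
    rois, origins, frames_idx = [], [], []
    for f, frame in enumerate(movie):
        det = _smooth_detect(frame, sigma_lo, sigma_hi)
        cand = _local_maxima(det, threshold, min_separation)
        n = 0
        for (r, c) in cand:
            if n >= max_per_frame:
                break
            r0, c0 = r - half, c - half
            if r0 < 0 or c0 < 0 or r0 + roi_size > ny or c0 + roi_size > nx:
                continue
            rois.append(frame[r0:r0 + roi_size, c0:c0 + roi_size])
            origins.append((r0, c0))
            frames_idx.append(f)
            n += 1
    if not rois:
        return ROIDataset(rois=np.zeros((0, 1, roi_size, roi_size)),
                          roi_origin=np.zeros((0, 2), int),
                          kind="blinking-emitter",
                          frame_index=np.zeros(0, int))
    return ROIDataset(rois=np.stack(rois)[:, None],
                      roi_origin=np.array(origins), kind="blinking-emitter",
                      frame_index=np.array(frames_idx))


def deskew_integer(stack: np.ndarray, geometry: ShearGeometry,
                   pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Remove the integer-pixel part of stage-scan shear from a stack.

    Slice j is rolled by the integer part of its cumulative lateral offset
    (in pixels); only integer shifts are applied so the photon statistics of
    the raw data are untouched. The sub-pixel residuals (in nm) are returned
    for the forward model to absorb.
    """
    stack = np.asarray(stack, float).copy()
    residual = np.zeros(stack.shape[0])
    for j in range(stack.shape[0]):
        off_px = j * geometry.dx_per_step / pixel_size
        ip = int(np.floor(off_px + 0.5))
        stack[j] = np.roll(stack[j], -ip, axis=-1)
        residual[j] = (off_px - ip) * pixel_size
    return stack, residual


def read_tiff(path) -> np.ndarray:
    import tifffile
    return tifffile.imread(path)


def write_tiff(path, data: np.ndarray):
    import tifffile
    tifffile.imwrite(path, np.asarray(data, np.float32))
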
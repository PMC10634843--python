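"""Loss functions and regularizers for PSF inverse modelling.

The data term is either the mean square error (voxel models) or the Poisson
negative log-likelihood (pupil-based models, accounting for shot noise).
Regularizers penalize voxel roughness and boundary energy, and enforce
smoothness of field-dependent aberration maps. Every function has a matching
``*_grad`` companion returning the exact analytic gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossSpec", "mse_loss", "mse_grad", "poisson_nll", "poisson_grad",
    "voxel_regularizers", "voxel_regularizers_grad",
    "fd_smoothness", "fd_smoothness_grad",
]

_MODEL_FLOOR = 1e-9


@dataclass
class LossSpec:
    """Which data term and regularizer weights a fit uses."""

    data_term: str = "poisson"       # "poisson" | "mse"
    smooth_weight: float = 0.0       # voxel second-difference energy
    edge_weight: float = 0.0         # voxel boundary-shell magnitude
    fd_smooth_weight: float = 0.0    # FD-map first-difference energy

    def __post_init__(self):
        if self.data_term not in ("poisson", "mse"):
            raise ValueError(f"unknown data term {self.data_term!r}")
        for w in (self.smooth_weight, self.edge_weight, self.fd_smooth_weight):
            if w < 0:
                raise ValueError("regularizer weights must be >= 0")


def mse_loss(model: np.ndarray, data: np.ndarray) -> float:
    """Mean of squared residuals over all pixels and ROIs."""
    if model.shape != data.shape:
        raise ValueError(f"shape mismatch {model.shape} vs {data.shape}")
    return float(np.mean((model - data) ** 2))


def mse_grad(model: np.ndarray, data: np.ndarray) -> np.ndarray:
    return 2.0 * (model - data) / model.size


def poisson_nll(model: np.ndarray, data: np.ndarray) -> float:
    """Poisson negative log-likelihood sum(mu - k log mu) / n_pixels.

    Constant terms in the data are dropped; non-positive model pixels are
    floored at 1e-9 with a warning (the forward models keep mu positive by
    construction, so the guard only fires on malformed input).
    """
    if model.shape != data.shape:
        raise ValueError(f"shape mismatch {model.shape} vs {data.shape}")
    if np.any(model <= 0):
        warnings.warn("non-positive model pixels floored in Poisson NLL",
                      RuntimeWarning, stacklevel=2)
    mu = np.maximum(model, _MODEL_FLOOR)
    return float(np.sum(mu - data * np.log(mu)) / model.size)


def poisson_grad(model: np.ndarray, data: np.ndarray) -> np.ndarray:
    mu = np.maximum(model, _MODEL_FLOOR)
    g = (1.0 - data / mu) / model.size
    return np.where(model > _MODEL_FLOOR, g, 0.0)


# ---------------------------------------------------------------------------
# Voxel regularizers


def _second_diff_energy(v: np.ndarray) -> float:
    e = 0.0
    for ax in range(v.ndim):
        d = np.diff(v, n=2, axis=ax)
        e += float(np.sum(d ** 2))
    return e


def _second_diff_energy_grad(v: np.ndarray) -> np.ndarray:
    g = np.zeros_like(v)
    for ax in range(v.ndim):
        d = np.diff(v, n=2, axis=ax)
        # adjoint of the [1, -2, 1] stencil
        sl = [slice(None)] * v.ndim

        def put(offset, coeff):
            sl[ax] = slice(offset, offset + d.shape[ax])
            g[tuple(sl)] += coeff * d

        put(0, 2.0)
        put(1, -4.0)
        put(2, 2.0)
        sl[ax] = slice(None)
    return g


def _edge_mask(shape: tuple[int, ...]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for ax in range(len(shape)):
        sl = [slice(None)] * len(shape)
        sl[ax] = 0
        m[tuple(sl)] = True
        sl[ax] = -1
        m[tuple(sl)] = True
    return m


def voxel_regularizers(values: np.ndarray, smooth_weight: float,
                       edge_weight: float) -> float:
    """Weighted voxel-model penalty: curvature energy + boundary magnitude.

    Smoothness: sum over axes of squared second differences (stencil
    [1, -2, 1] along each axis, no wraparound). Edge suppression: squared
    voxel values on the one-voxel boundary shell of the volume. Both reduce
    overfitting and keep energy away from the ROI edges where wraparound of
    the Fourier shifts would alias.
    """
    if smooth_weight < 0 or edge_weight < 0:
        raise ValueError("weights must be >= 0")
    out = 0.0
    if smooth_weight:
        out += smooth_weight * _second_diff_energy(values)
    if edge_weight:
        out += edge_weight * float(np.sum(values[_edge_mask(values.shape)] ** 2))
    return out


def voxel_regularizers_grad(values: np.ndarray, smooth_weight: float,
                            edge_weight: float) -> np.ndarray:
    g = np.zeros_like(values)
    if smooth_weight:
        g += smooth_weight * _second_diff_energy_grad(values)
    if edge_weight:
        m = _edge_mask(values.shape)
        g[m] += 2.0 * edge_weight * values[m]
    return g


# ---------------------------------------------------------------------------
# Field-dependent map smoothness


def fd_smoothness(maps: np.ndarray) -> float:
    """Sum over modes of squared first differences of each map, both axes."""
    maps = np.asarray(maps, float)
    e = 0.0
    for ax in (-2, -1):
        e += float(np.sum(np.diff(maps, axis=ax) ** 2))
    return e


def fd_smoothness_grad(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, float)
    g = np.zeros_like(maps)
    for ax in (-2, -1):
        d = np.diff(maps, axis=ax)
        sl_lo = [slice(None)] * maps.ndim
        sl_hi = [slice(None)] * maps.ndim
        sl_lo[ax] = slice(0, d.shape[ax])
        sl_hi[ax] = slice(1, d.shape[ax] + 1)
        g[tuple(sl_lo)] -= 2 * d
        g[tuple(sl_hi)] += 2 * d
    return g
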
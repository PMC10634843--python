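"""Parameter packing for joint fits: grouping, linking, positivity, scaling.

Every free quantity of a fit (model coefficients, per-emitter positions,
photons, backgrounds, ...) lives in a named :class:`ParamGroup`. Groups
sharing a ``link`` label are one optimization variable unpacked into each
member, so linked parameters agree exactly by construction. Positive
quantities are reparameterized through a softplus, keeping the optimization
unconstrained and the gradients exact (no clipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ParamGroup", "ParameterSet", "softplus", "inv_softplus"]


def softplus(u: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + e^u)."""
    u = np.asarray(u, float)
    return np.where(u > 30, u, np.log1p(np.exp(np.minimum(u, 30))))


def softplus_grad(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, float)
    return 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))


def inv_softplus(y: np.ndarray) -> np.ndarray:
    """Inverse of softplus; y must be > 0."""
    y = np.asarray(y, float)
    y = np.maximum(y, 1e-12)
    return np.where(y > 30, y, np.log(np.expm1(np.minimum(y, 30))))


@dataclass
class ParamGroup:
    """One named block of fit parameters.

    ``scale`` is a characteristic magnitude used to condition the packed
    vector (the optimizer sees value/scale). ``link`` ties whole groups
    together across the set; ``tie`` ties elements *within* the group: an
    integer label array of the group's shape, where elements sharing a label
    are one variable (their gradients sum, their values agree exactly).
    """

    name: str
    value: np.ndarray
    free: bool = True
    positive: bool = False
    scale: float = 1.0
    link: Optional[str] = None
    tie: Optional[np.ndarray] = None

    def __post_init__(self):
        self.value = np.atleast_1d(np.asarray(self.value, dtype=float))
        if self.positive and np.any(self.value < 0):
            raise ValueError(f"group {self.name!r} marked positive has "
                             "negative initial values")
        if self.tie is not None:
            self.tie = np.asarray(self.tie, int)
            if self.tie.shape != self.value.shape:
                raise ValueError(f"tie labels of group {self.name!r} must "
                                 "match the value shape")

    def _reduce(self, arr: np.ndarray) -> np.ndarray:
        """First-occurrence representative of each tie class."""
        if self.tie is None:
            return arr
        _, first = np.unique(self.tie.ravel(), return_index=True)
        return arr.ravel()[np.sort(first)]

    def _expand(self, reduced: np.ndarray) -> np.ndarray:
        if self.tie is None:
            return reduced
        labels, first, inverse = np.unique(self.tie.ravel(),
                                           return_index=True,
                                           return_inverse=True)
        # map unique-label order to first-occurrence order
        perm = np.argsort(first)           # occurrence rank -> unique idx
        rank = np.empty_like(perm)
        rank[perm] = np.arange(len(perm))
        return reduced[rank][inverse].reshape(self.value.shape)

    def _reduce_grad(self, grad: np.ndarray) -> np.ndarray:
        if self.tie is None:
            return grad
        labels, first, inverse = np.unique(self.tie.ravel(),
                                           return_index=True,
                                           return_inverse=True)
        sums = np.bincount(inverse, weights=grad.ravel(),
                           minlength=len(labels))
        perm = np.argsort(first)
        rank = np.empty_like(perm)
        rank[perm] = np.arange(len(perm))
        # sums is in unique-label order; reorder to first-occurrence order
        out = np.empty_like(sums)
        out[rank] = sums
        return out


class ParameterSet:
    """Ordered collection of parameter groups with pack/unpack machinery."""

    def __init__(self):
        self.groups: dict[str, ParamGroup] = {}

    def add(self, name: str, value, free: bool = True, positive: bool = False,
            scale: float = 1.0, link: str | None = None,
            tie: np.ndarray | None = None) -> ParamGroup:
        if name in self.groups:
            raise ValueError(f"duplicate group {name!r}")
        g = ParamGroup(name, np.asarray(value, float), free=free,
                       positive=positive, scale=scale, link=link, tie=tie)
        self.groups[name] = g
        return g

    def __getitem__(self, name: str) -> ParamGroup:
        return self.groups[name]

    # -- link bookkeeping ---------------------------------------------------

    def _variables(self) -> list[list[ParamGroup]]:
        """Free groups collected into link classes (each class = 1 variable)."""
        seen: dict[str, list[ParamGroup]] = {}
        order: list[list[ParamGroup]] = []
        for g in self.groups.values():
            if not g.free:
                continue
            if g.link is None:
                order.append([g])
                continue
            if g.link in seen:
                ref = seen[g.link][0]
                if ref.value.shape != g.value.shape:
                    raise ValueError(
                        f"linked groups {ref.name!r}/{g.name!r} shape mismatch")
                seen[g.link].append(g)
            else:
                seen[g.link] = [g]
                order.append(seen[g.link])
        return order

    # -- packing ------------------------------------------------------------

    def pack(self) -> np.ndarray:
        parts = []
        for cls in self._variables():
            g = cls[0]
            v = g._reduce(g.value)
            v = inv_softplus(v) if g.positive else v
            parts.append((v / g.scale).ravel())
        return np.concatenate(parts) if parts else np.zeros(0)

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Write theta back into all groups; returns name -> value view."""
        i = 0
        for cls in self._variables():
            g0 = cls[0]
            n = (g0.value.size if g0.tie is None
                 else len(np.unique(g0.tie)))
            raw = theta[i:i + n] * g0.scale
            red = softplus(raw) if g0.positive else raw
            val = (red.reshape(g0.value.shape) if g0.tie is None
                   else g0._expand(red))
            for g in cls:
                g.value = val.copy()
            i += n
        return {name: g.value for name, g in self.groups.items()}

    def pack_grad(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        """Chain per-group value-gradients into the packed-vector gradient."""
        parts = []
        for cls in self._variables():
            g0 = cls[0]
            acc = np.zeros_like(g0.value)
            for g in cls:
                if g.name in grads:
                    acc = acc + np.asarray(grads[g.name], float).reshape(acc.shape)
            red = g0._reduce_grad(acc)
            if g0.positive:
                raw = inv_softplus(g0._reduce(g0.value))
                red = red * softplus_grad(raw)
            parts.append((red * g0.scale).ravel())
        return np.concatenate(parts) if parts else np.zeros(0)

    def values(self) -> dict[str, np.ndarray]:
        return {name: g.value for name, g in self.groups.items()}
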
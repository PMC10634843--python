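"""Zernike polynomials on the unit disk, with Noll and Fringe mode orderings.

Conventions
-----------
All polynomials carry the Noll RMS normalization: piston is identically 1 and
every other mode has unit root-mean-square over the unit disk, so a pupil-phase
coefficient is directly the RMS wavefront contribution of that mode in radians.
A mode is identified by its radial order ``n`` and signed azimuthal order
``m``; ``m >= 0`` selects the ``cos(m*theta)`` branch, ``m < 0`` the
``sin(|m|*theta)`` branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZernikeBasis",
    "zernike_polynomial",
    "noll_modes",
    "fringe_modes",
    "noll_to_nm",
    "fringe_index",
    "count_zernike_modes",
    "fringe_mode_range",
    "mode_name",
    "resolve_mode_name",
]


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Radial part R_n^{|m|}(rho) via the explicit factorial sum."""
    m = abs(m)
    if (n - m) % 2:
        return np.zeros_like(rho)
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)))
        out = out + c * rho ** (n - 2 * k)
    return out


def zernike_polynomial(n: int, m: int, rho, theta) -> np.ndarray:
    """Evaluate the RMS-normalized Zernike mode (n, m) at (rho, theta).

    Parameters
    ----------
    n, m
        Radial and signed azimuthal order; requires ``|m| <= n`` and
        ``n - |m|`` even.
    rho
        Radial coordinate in [0, 1] (values outside raise).
    theta
        Azimuth in radians.
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if n < 0 or abs(m) > n or (n - abs(m)) % 2:
        raise ValueError(f"invalid Zernike mode (n={n}, m={m})")
    if np.any(rho < 0) or np.any(rho > 1 + 1e-12):
        raise ValueError("rho must lie in [0, 1]")
    norm = 1.0 if n == 0 and m == 0 else (
        math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1)))
    r = _radial_poly(n, m, rho)
    if m == 0:
        ang = 1.0
    elif m > 0:
        ang = np.cos(m * theta)
    else:
        ang = np.sin(-m * theta)
    return norm * r * ang


# ---------------------------------------------------------------------------
# Mode orderings


def noll_modes(max_radial_order: int) -> list[tuple[int, int]]:
    """Ordered (n, m) list for Noll indices 1..count, radial order <= max.

    Noll's rule: modes are sorted by n, then by |m|; within a (n, |m|) pair the
    cosine mode (m > 0) receives the even index and the sine mode the odd one.
    """
    if max_radial_order < 0:
        raise ValueError("max_radial_order must be >= 0")
    modes: list[tuple[int, int]] = []
    for n in range(max_radial_order + 1):
        for am in range(n % 2, n + 1, 2):
            if am == 0:
                modes.append((n, 0))
            else:
                j_next = len(modes) + 1
                pair = [(n, am), (n, -am)] if j_next % 2 == 0 else [(n, -am), (n, am)]
                modes.extend(pair)
    return modes


def noll_to_nm(j: int) -> tuple[int, int]:
    """(n, m) of Noll index ``j`` (1-based)."""
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    while (n + 1) * (n + 2) // 2 < j:
        n += 1
    return noll_modes(n)[j - 1]


def fringe_index(n: int, m: int) -> int:
    """Fringe (University of Arizona) index of mode (n, m), 1-based."""
    am = abs(m)
    return (1 + (n + am) // 2) ** 2 - 2 * am + (0 if m >= 0 else 1)


def fringe_modes(max_index: int) -> list[tuple[int, int]]:
    """Ordered (n, m) list for Fringe indices 1..max_index."""
    if max_index < 1:
        raise ValueError("max_index must be >= 1")
    table: dict[int, tuple[int, int]] = {}
    n = 0
    while len(table) < max_index:
        for am in range(n % 2, n + 1, 2):
            for m in ([0] if am == 0 else [am, -am]):
                f = fringe_index(n, m)
                if f <= max_index:
                    table[f] = (n, m)
        n += 1
        if n > 4 * max_index:  # safety; never reached for sane input
            raise RuntimeError("failed to enumerate Fringe table")
    return [table[i] for i in range(1, max_index + 1)]


def count_zernike_modes(max_radial_order: int, scheme: str = "noll") -> int:
    """Number of Zernike modes with radial order <= max_radial_order.

    Both Noll and Fringe enumerate the same (n, m) set below a radial-order
    cap, so the count is (R+1)(R+2)/2 regardless of scheme; the scheme argument
    is validated for interface symmetry with the ordering helpers.
    """
    if max_radial_order < 0:
        raise ValueError("max_radial_order must be >= 0")
    if scheme.lower() not in ("noll", "fringe"):
        raise ValueError(f"unknown scheme {scheme!r}; use 'noll' or 'fringe'")
    r = max_radial_order
    return (r + 1) * (r + 2) // 2


# Named Fringe modes (canonical name first, aliases after).
_FRINGE_NAMES: dict[int, tuple[str, ...]] = {
    1: ("piston",),
    2: ("tilt x", "tip"),
    3: ("tilt y", "tilt"),
    4: ("defocus", "power"),
    5: ("vertical astigmatism", "astigmatism 0", "astigmatism vertical"),
    6: ("oblique astigmatism", "astigmatism 45", "astigmatism oblique"),
    7: ("horizontal coma", "coma x"),
    8: ("vertical coma", "coma y"),
    9: ("primary spherical", "spherical"),
    10: ("oblique trefoil", "trefoil x"),
    11: ("vertical trefoil", "trefoil y"),
    12: ("secondary astigmatism x", "secondary vertical astigmatism"),
    13: ("secondary astigmatism y", "secondary oblique astigmatism"),
    14: ("secondary coma x", "secondary horizontal coma"),
    15: ("secondary coma y", "secondary vertical coma"),
    16: ("secondary spherical",),
    17: ("tetrafoil x",),
    18: ("tetrafoil y",),
    19: ("secondary trefoil x",),
    20: ("secondary trefoil y",),
    21: ("tertiary astigmatism x",),
    22: ("tertiary astigmatism y",),
    23: ("tertiary coma x",),
    24: ("tertiary coma y",),
    25: ("third-order spherical", "tertiary spherical"),
}


def _canon(name: str) -> str:
    return " ".join(name.lower().replace("-", " ").replace("_", " ").split())


_NAME_TO_FRINGE: dict[str, int] = {
    _canon(alias): idx for idx, names in _FRINGE_NAMES.items() for alias in names
}


def mode_name(fringe_idx: int) -> str:
    """Canonical name of a Fringe-indexed mode (or ``Z<f>`` if unnamed)."""
    names = _FRINGE_NAMES.get(fringe_idx)
    return names[0] if names else f"Z{fringe_idx}"


def resolve_mode_name(name: str) -> int:
    """Fringe index of a named aberration mode."""
    key = _canon(name)
    if key not in _NAME_TO_FRINGE:
        known = ", ".join(sorted({a for v in _FRINGE_NAMES.values() for a in v}))
        raise KeyError(f"unknown mode name {name!r}; known names: {known}")
    return _NAME_TO_FRINGE[key]


def fringe_mode_range(first_mode: str, last_mode: str) -> list[tuple[int, int]]:
    """Contiguous Fringe-ordered (n, m) list between two named modes, inclusive.

    Example: the span from vertical astigmatism through third-order spherical
    covers Fringe indices 5..25, i.e. 21 modes.
    """
    i0 = resolve_mode_name(first_mode)
    i1 = resolve_mode_name(last_mode)
    if i1 < i0:
        raise ValueError(f"{last_mode!r} precedes {first_mode!r} in Fringe order")
    return fringe_modes(i1)[i0 - 1:]


# ---------------------------------------------------------------------------


@dataclass
class ZernikeBasis:
    """A stack of Zernike modes evaluated on a pupil grid.

    Attributes
    ----------
    scheme : str
        Mode-ordering convention, ``"noll"`` or ``"fringe"``.
    modes : list of (n, m)
        Ordered mode list.
    values : ndarray, shape (n_modes, N, N)
        Each polynomial sampled on the aperture-scaled grid; zero outside the
        unit disk.
    """

    scheme: str
    modes: list[tuple[int, int]]
    values: np.ndarray = field(repr=False)

    @classmethod
    def from_grid(cls, rho: np.ndarray, theta: np.ndarray,
                  modes: list[tuple[int, int]] | None = None,
                  max_radial_order: int = 8,
                  scheme: str = "noll") -> "ZernikeBasis":
        """Evaluate a basis on precomputed polar pupil coordinates.

        ``rho`` is the pupil radius scaled so the aperture rim is 1; samples
        with rho > 1 evaluate to 0.
        """
        if modes is None:
            if scheme.lower() == "noll":
                modes = noll_modes(max_radial_order)
            elif scheme.lower() == "fringe":
                modes = [nm for nm in
                         fringe_modes(4 * count_zernike_modes(max_radial_order))
                         if nm[0] <= max_radial_order]
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
        inside = rho <= 1.0
        rho_c = np.where(inside, rho, 0.0)
        vals = np.stack([
            np.where(inside, zernike_polynomial(n, m, rho_c, theta), 0.0)
            for n, m in modes
        ])
        return cls(scheme=scheme.lower(), modes=list(modes), values=vals)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def compose(self, coeffs: np.ndarray) -> np.ndarray:
        """Sum_p c_p Z_p on the grid."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape[-1] != self.n_modes:
            raise ValueError(
                f"expected {self.n_modes} coefficients, got {coeffs.shape[-1]}")
        return np.tensordot(coeffs, self.values, axes=(-1, 0))

    def index_of(self, n: int, m: int) -> int:
        try:
            return self.modes.index((n, m))
        except ValueError:
            raise KeyError(f"mode (n={n}, m={m}) not in basis") from None
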
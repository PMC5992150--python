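"""Uniform-lattice scalar fields and the discrete operators the model is built on.

All fields (vessel order parameter ``phi``, tissue-cell order parameter
``psi`` and angiogenic-factor concentration ``T``) live on the same
node-centred uniform grid with isotropic spacing ``h`` (micrometres).  Node
``i`` along an axis sits at physical coordinate ``(i + 0.5) * h``; axis 0 is
the vertical axis with "top" at index 0.  Every face of the box is a no-flux
(mirror/Neumann) boundary, which keeps the conservative interface dynamics
exactly mass conserving and prevents artificial leakage of the angiogenic
factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Grid",
    "ScalarField",
    "laplacian",
    "gradient",
    "gradient_field",
    "integrate",
]


@dataclass(frozen=True)
class Grid:
    """Uniform node-centred lattice with isotropic spacing.

    Parameters
    ----------
    shape : tuple of int
        Number of nodes per axis (2 or 3 axes, each >= 8).
    h : float
        Grid spacing in micrometres (> 0).
    """

    shape: tuple[int, ...]
    h: float

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got {len(self.shape)} axes")
        if any(int(n) < 8 for n in self.shape):
            raise ValueError(f"need >= 8 nodes per axis, got {self.shape}")
        if not self.h > 0:
            raise ValueError("spacing h must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def dims(self) -> int:
        return len(self.shape)

    @property
    def extents(self) -> tuple[float, ...]:
        """Physical box size per axis in micrometres (= shape * h)."""
        return tuple(n * self.h for n in self.shape)

    @property
    def measure(self) -> float:
        """Domain area (um^2) or volume (um^3)."""
        return float(np.prod(self.extents))

    def node_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of node centres along one axis."""
        return (np.arange(self.shape[axis]) + 0.5) * self.h

    def position_to_index(self, p: np.ndarray) -> np.ndarray:
        """Fractional index coordinates of a physical position (um)."""
        return np.asarray(p, dtype=float) / self.h - 0.5

    def contains(self, p: np.ndarray) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= 0.0) and np.all(p <= np.asarray(self.extents)))

    def clamp(self, p: np.ndarray) -> np.ndarray:
        """Clamp a physical position onto the closed box."""
        hi = np.asarray(self.extents)
        return np.minimum(np.maximum(np.asarray(p, dtype=float), 0.0), hi)


@dataclass
class ScalarField:
    """A lattice-sampled scalar with a physical grid and a label."""

    grid: Grid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def full(cls, grid: Grid, value: float, name: str = "") -> "ScalarField":
        return cls(grid, np.full(grid.shape, float(value)), name)

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.name)


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.isfinite(a).all():
        raise FloatingPointError(f"non-finite values in {what}")


def laplacian_array(values: np.ndarray, h: float) -> np.ndarray:
    """Second-order central-difference Laplacian with mirror (no-flux) faces.

    Ghost nodes are the mirror image of the first interior node, so the
    normal derivative vanishes on every face and the discrete divergence
    theorem holds exactly: ``sum(laplacian) == 0`` to round-off.
    """
    padded = np.pad(values, 1, mode="edge")
    out = np.zeros_like(values, dtype=float)
    nd = values.ndim
    core = tuple(slice(1, -1) for _ in range(nd))
    for ax in range(nd):
        lo = tuple(
            slice(0, -2) if a == ax else slice(1, -1) for a in range(nd)
        )
        hi = tuple(
            slice(2, None) if a == ax else slice(1, -1) for a in range(nd)
        )
        out += padded[lo] + padded[hi]
    out -= 2 * nd * padded[core]
    out /= h * h
    return out


def laplacian(f: ScalarField) -> ScalarField:
    """Discrete Laplacian of a field (no-flux boundaries)."""
    _check_finite(f.values, f.name or "field")
    return ScalarField(f.grid, laplacian_array(f.values, f.grid.h), f"lap({f.name})")


def gradient_field(f: ScalarField) -> list[np.ndarray]:
    """Central-difference gradient components on the nodes (no-flux faces)."""
    padded = np.pad(f.values, 1, mode="edge")
    nd = f.values.ndim
    comps = []
    for ax in range(nd):
        lo = tuple(slice(0, -2) if a == ax else slice(1, -1) for a in range(nd))
        hi = tuple(slice(2, None) if a == ax else slice(1, -1) for a in range(nd))
        comps.append((padded[hi] - padded[lo]) / (2.0 * f.grid.h))
    return comps


def gradient(f: ScalarField, p: np.ndarray) -> np.ndarray:
    """Gradient of ``f`` interpolated (multilinear) to physical position ``p``.

    ``p`` must lie inside the domain.
    """
    p = np.asarray(p, dtype=float)
    if not f.grid.contains(p):
        raise ValueError(f"position {p} outside domain {f.grid.extents}")
    comps = gradient_field(f)
    return interp_at(comps, f.grid, p)


def interp_at(arrays: list[np.ndarray] | np.ndarray, grid: Grid, p: np.ndarray) -> np.ndarray:
    """Multilinear interpolation of one or several node arrays at position p."""
    idx = grid.position_to_index(np.asarray(p, dtype=float))
    coords = idx.reshape(-1, 1)
    if isinstance(arrays, np.ndarray):
        return map_coordinates(arrays, coords, order=1, mode="nearest")[0]
    return np.array(
        [map_coordinates(a, coords, order=1, mode="nearest")[0] for a in arrays]
    )


def integrate(f: ScalarField) -> float:
    """Lattice integral: sum of node values times h**dims."""
    return float(f.values.sum() * f.grid.h ** f.grid.dims)
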
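"""Hypoxic tissue cells and the two irrigation rules that silence them.

Tissue cells are static spheres that secrete angiogenic factor while
hypoxic.  A cell is deactivated (irreversibly) once it is within the
average oxygen diffusion length ``d`` (default 25 um) of vasculature:

* Rule 1 - of a vessel medial line that actually carries blood
  (|Q| above a numerical zero threshold), so deactivation requires loops
  and a flow path; irrigation regulates VEGF production.
* Rule 2 - of any vessel node (phi > 0), flowing or not; proximity alone
  silences the cell.

For identical geometry and flow the Rule-1 deactivation set is a subset of
the Rule-2 set, since flowing medial points are a subset of vessel points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .grid_fields import Grid, ScalarField, interp_at

__all__ = ["TissueCell", "HypoxiaParams", "update_hypoxia", "distance_to_mask"]


@dataclass
class TissueCell:
    """A static spherical tissue cell (positions and radius in um)."""

    id: int
    center: np.ndarray
    radius: float
    hypoxic: bool = True
    deactivation_time: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    def deactivate(self, t: float) -> None:
        if self.hypoxic:
            self.hypoxic = False
            self.deactivation_time = t


@dataclass
class HypoxiaParams:
    """rule: 1 (flow-dependent) or 2 (proximity-only); d_oxygen in um."""

    rule: int = 1
    d_oxygen: float = 25.0
    Q_min_rel: float = 1.0e-6  # flowing threshold, relative to max |Q|

    def __post_init__(self) -> None:
        if self.rule not in (1, 2):
            raise ValueError("HypoxiaParams.rule must be 1 or 2")
        if not self.d_oxygen > 0:
            raise ValueError("HypoxiaParams.d_oxygen must be positive")


def distance_to_mask(mask: np.ndarray, grid: Grid, points: np.ndarray) -> np.ndarray:
    """Euclidean distance (um) from each physical point to the True set.

    Uses the sampled distance transform of the complement, interpolated to
    the (off-grid) points; exact to within one grid spacing.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not mask.any():
        return np.full(len(points), np.inf)
    edt = distance_transform_edt(~mask, sampling=grid.h)
    return np.array([interp_at(edt, grid, p) for p in points])


def _flowing_mask(grid: Grid, graph, flow) -> np.ndarray:
    """Rasterise the medial points of flowing edges onto the grid."""
    mask = np.zeros(grid.shape, dtype=bool)
    for u, v, k in flow.flowing:
        path = graph.g.edges[u, v, k]["path"]
        mask[tuple(path.T)] = True
    return mask


def update_hypoxia(state, graph=None, flow=None):
    """Deactivate every hypoxic cell irrigated under the active rule.

    Rule 2 needs only the current phi field; Rule 1 additionally needs the
    current vessel graph and its flow solution.  Distances are measured
    from the cell centre.  Mutates ``state`` in place and returns the list
    of cells deactivated in this update.
    """
    params = state.params.hypoxia
    hypoxic = [c for c in state.cells if c.hypoxic]
    if not hypoxic:
        return []
    if params.rule == 2:
        mask = state.phi.values > 0.0
    else:
        if graph is None or flow is None:
            raise ValueError("Rule 1 requires a vessel graph and a flow solution")
        mask = _flowing_mask(state.grid, graph, flow)
    centers = np.array([c.center for c in hypoxic])
    dist = distance_to_mask(mask, state.grid, centers)
    newly = []
    for cell, dc in zip(hypoxic, dist):
        if dc <= params.d_oxygen:
            cell.deactivate(state.t)
            state.invalidate_source_cache(cell.id)
            state.log_hypoxia_event(cell)
            newly.append(cell)
    return newly
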
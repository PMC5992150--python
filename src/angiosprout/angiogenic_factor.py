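"""Diffusion, consumption and hypoxic-cell sources of the angiogenic factor.

The VEGF-like factor ``T`` obeys a reaction-diffusion equation

    dT/dt = D * lap(T) - alpha_T * phi * T * Theta(phi)

(consumption only inside vessels, where phi > 0), with the concentration
clamped to ``T_s`` on the nodes around the centre of every *active*
hypoxic tissue cell.  ``T`` is reported throughout in units of ``T_s``.

Because sources are Dirichlet clamps and consumption is linear, the field
obeys a maximum principle (0 <= T <= T_s) and relaxes monotonically to a
steady profile when phi and the source set are static.  The factor is a
slow diffuser (matrix-binding isoforms), so the default ``D`` makes the
gradient field quasi-static on the sprouting time scale without becoming
uniform across the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_fields import Grid, ScalarField, laplacian_array

__all__ = [
    "FactorParams",
    "step_T",
    "consumption_mask",
    "stable_dt_T",
    "source_node_indices",
    "apply_sources",
]


@dataclass
class FactorParams:
    """Angiogenic-factor parameters.

    D : diffusion constant (um^2/s).  The factor is matrix-bound and
        diffuses slowly: the default keeps each cell's concentration halo
        localised (tens of um) over a day-long simulation, so gradients
        point toward individual hypoxic cells instead of saturating the
        whole box.
    alpha_T : consumption rate inside vessels (1/s).  The default sets
        the screening length sqrt(D/alpha_T) ~ 3 um: vessels absorb the
        factor within roughly a tip radius, so vessel interiors are
        shadowed (proliferation acts in a thin wall rim) while a
        migrating tip can still sense the gradient across its own
        freshly laid disc.
    T_s : source clamp concentration (the unit of T; default 1).
    source_radius : radius (um) of the clamped node set around each active
        cell centre; the clamp models secretion at the cell centre, so the
        default is half the tissue-cell radius.
    """

    D: float = 0.05
    alpha_T: float = 0.006
    T_s: float = 1.0
    source_radius: float = 5.0

    def __post_init__(self) -> None:
        for name in ("D", "alpha_T", "T_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"FactorParams.{name} must be strictly positive")
        if self.source_radius <= 0:
            raise ValueError("FactorParams.source_radius must be positive")

    @property
    def decay_length(self) -> float:
        """Consumption screening length sqrt(D / alpha_T) inside vessels (um)."""
        return float(np.sqrt(self.D / self.alpha_T))


def consumption_mask(phi: ScalarField) -> ScalarField:
    """phi * Theta(phi): the per-node vessel weight of factor consumption."""
    return ScalarField(
        phi.grid, np.where(phi.values > 0.0, phi.values, 0.0), "consumption"
    )


def source_node_indices(
    grid: Grid, center: np.ndarray, radius: float
) -> tuple[np.ndarray, ...]:
    """Node index tuple of all nodes within ``radius`` um of a point."""
    center = np.asarray(center, dtype=float)
    lo = np.maximum(np.floor((center - radius) / grid.h - 0.5).astype(int), 0)
    hi = np.minimum(
        np.ceil((center + radius) / grid.h - 0.5).astype(int) + 1,
        np.asarray(grid.shape),
    )
    ranges = [np.arange(lo[a], hi[a]) for a in range(grid.dims)]
    mesh = np.meshgrid(*ranges, indexing="ij")
    coords = np.stack([(m + 0.5) * grid.h for m in mesh], axis=-1)
    keep = np.linalg.norm(coords - center, axis=-1) <= radius
    return tuple(m[keep] for m in mesh)


def apply_sources(T: ScalarField, source_nodes, T_s: float) -> None:
    """Dirichlet reset: clamp T to T_s on every active source node set."""
    for idx in source_nodes:
        T.values[idx] = T_s


def step_T(state, dt: float):
    """Advance T by one explicit Euler step of length ``dt`` seconds.

    Operator split per step: (i) diffusion + consumption, (ii) clip tiny
    negative undershoot at 0, (iii) re-clamp active sources at T_s.
    Mutates ``state`` in place and returns it.
    """
    params = state.params.factor
    Tv = state.T.values
    dT = params.D * laplacian_array(Tv, state.grid.h)
    dT -= params.alpha_T * np.where(state.phi.values > 0.0, state.phi.values, 0.0) * Tv
    Tv += dt * dT
    if not np.isfinite(Tv).all():
        raise FloatingPointError(
            f"T became non-finite at t={state.t:.1f}s: unstable dt={dt}"
        )
    if Tv.min() < -1e-12 * params.T_s:
        raise FloatingPointError(
            f"T undershoot {Tv.min():.3e} below tolerance at t={state.t:.1f}s"
        )
    np.clip(Tv, 0.0, None, out=Tv)
    apply_sources(state.T, state.active_source_nodes(), params.T_s)
    return state


def stable_dt_T(grid: Grid, params: FactorParams, safety: float = 0.9) -> float:
    """Explicit diffusion stability bound h^2 / (2 * dims * D), times safety."""
    return safety * grid.h**2 / (2.0 * grid.dims * params.D)
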
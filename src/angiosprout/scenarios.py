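"""Programmatic construction of initial conditions.

Three canonical layouts:

* :func:`random_2d` -- 375 x 375 um^2 box, parent capillary along the
  bottom edge, seeded random non-overlapping hypoxic cells kept at least
  the oxygen diffusion length away from the capillary so that every cell
  starts hypoxic under both irrigation rules.
* :func:`regular_2d` -- the same box with eight parallel rows of ten
  cells and an empty middle band (three row spacings tall) between rows
  4 and 5; used to show that cell placement templates the network.
* :func:`random_3d` -- 250 x 250 x 125 um^3 box with a straight parent
  capillary through the centre spanning one horizontal axis.

All placement is by seeded rejection sampling, so a scenario is fully
deterministic given (parameters, seed).  Axis 0 is vertical with the top
of the box at index 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .grid_fields import Grid, ScalarField
from .endothelial_phase import build_psi
from .hypoxia_control import TissueCell
from .state import ModelParams, SimulationState

__all__ = ["Scenario", "random_2d", "regular_2d", "random_3d", "build_state"]

BOX_2D = 375.0  # um
BOX_3D = (125.0, 250.0, 250.0)  # vertical, capillary axis, transverse (um)
H_2D = 2.5  # um; resolves the eps = 3.75 um wall with >= 2 nodes
H_3D = 5.0  # um; coarser grid keeps 3D runs desk-sized
EPS_3D = 6.0


@dataclass
class Scenario:
    """A reproducible initial condition: grid, vessel, cells, parameters."""

    name: str
    grid: Grid
    vessel_kind: str  # "bottom_stripe" | "central_cylinder"
    vessel_size: float  # stripe thickness or cylinder radius (um)
    cell_centers: np.ndarray
    cell_radius: float
    params: ModelParams
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_centers = np.asarray(self.cell_centers, dtype=float).reshape(
            -1, self.grid.dims
        )

    def with_params(self, params: ModelParams) -> "Scenario":
        return replace(self, params=params)

    # -- serialisation ---------------------------------------------------
    def to_yaml(self) -> str:
        from dataclasses import asdict

        doc = {
            "name": self.name,
            "seed": self.seed,
            "grid": {"shape": list(self.grid.shape), "h": self.grid.h},
            "vessel": {"kind": self.vessel_kind, "size": self.vessel_size},
            "cells": {
                "radius": self.cell_radius,
                "centers": self.cell_centers.tolist(),
            },
            "params": {
                "phase": asdict(self.params.phase),
                "factor": asdict(self.params.factor),
                "tip": asdict(self.params.tip),
                "hypoxia": asdict(self.params.hypoxia),
                "cell_radius": self.params.cell_radius,
                "agent_every": self.params.agent_every,
                "irrigation_interval": self.params.irrigation_interval,
                "dt": self.params.dt,
            },
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        from .endothelial_phase import PhaseParams
        from .angiogenic_factor import FactorParams
        from .tip_agents import TipParams
        from .hypoxia_control import HypoxiaParams

        doc = yaml.safe_load(text)
        p = doc["params"]
        params = ModelParams(
            phase=PhaseParams(**p["phase"]),
            factor=FactorParams(**p["factor"]),
            tip=TipParams(**p["tip"]),
            hypoxia=HypoxiaParams(**p["hypoxia"]),
            cell_radius=p["cell_radius"],
            agent_every=p["agent_every"],
            irrigation_interval=p["irrigation_interval"],
            dt=p["dt"],
        )
        return cls(
            name=doc["name"],
            grid=Grid(tuple(doc["grid"]["shape"]), doc["grid"]["h"]),
            vessel_kind=doc["vessel"]["kind"],
            vessel_size=doc["vessel"]["size"],
            cell_centers=np.asarray(doc["cells"]["centers"], dtype=float),
            cell_radius=doc["cells"]["radius"],
            params=params,
            seed=doc["seed"],
        )


def _default_params_2d() -> ModelParams:
    return ModelParams()


def _reject_sample(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_pair: float,
    accept_fn,
    max_attempts: int = 20000,
) -> np.ndarray:
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} cells after {max_attempts} attempts "
                "(density too high)"
            )
        attempts += 1
        p = lo + rng.random(len(lo)) * (hi - lo)
        if not accept_fn(p):
            continue
        if any(np.linalg.norm(p - q) < min_pair for q in placed):
            continue
        placed.append(p)
    return np.array(placed)


def random_2d(
    n_cells: int = 30,
    seed: int = 0,
    params: ModelParams | None = None,
    cell_radius: float = 10.0,
    box: float = BOX_2D,
) -> Scenario:
    """Random hypoxic-cell layout in a square 2D box with a bottom capillary.

    ``box`` is the side length in um (default the standard 375 um domain;
    parameter-sweep batteries use a smaller box to stay desk-sized --
    the reported morphometrics are densities, per mm^2).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    params = params or _default_params_2d()
    grid = Grid((int(box / H_2D), int(box / H_2D)), H_2D)
    stripe = 4.0 * params.tip.R_c  # capillary thickness (um)
    d = params.hypoxia.d_oxygen
    rng = np.random.default_rng(seed)
    H = grid.extents[0]
    # centres >= cell_radius from walls, and > d from the capillary surface
    lo = np.array([cell_radius, cell_radius])
    hi = np.array([H - stripe - d - cell_radius, grid.extents[1] - cell_radius])
    centers = _reject_sample(
        rng, n_cells, lo, hi, 2.0 * cell_radius, lambda p: True
    )
    return Scenario(
        name=f"random_2d_n{n_cells}_s{seed}_b{box:g}",
        grid=grid,
        vessel_kind="bottom_stripe",
        vessel_size=stripe,
        cell_centers=centers,
        cell_radius=cell_radius,
        params=params,
        seed=seed,
    )


def regular_2d(
    params: ModelParams | None = None, cell_radius: float = 10.0
) -> Scenario:
    """Eight rows of ten cells with an empty middle band (rows 4/5 gap).

    Row spacing is 30 um inside each four-row band; the empty band between
    rows 4 and 5 is 90 um (= 3 row spacings).  The lattice is mirror
    symmetric about the vertical centreline.
    """
    params = params or _default_params_2d()
    grid = Grid((int(BOX_2D / H_2D), int(BOX_2D / H_2D)), H_2D)
    H = grid.extents[0]
    W = grid.extents[1]
    # heights above the bottom edge of the box
    lower = [75.0, 105.0, 135.0, 165.0]
    upper = [255.0, 285.0, 315.0, 345.0]
    xs = (np.arange(10) + 0.5) * (W / 10.0)
    centers = [
        np.array([H - y, x]) for y in lower + upper for x in xs
    ]
    return Scenario(
        name="regular_2d",
        grid=grid,
        vessel_kind="bottom_stripe",
        vessel_size=4.0 * params.tip.R_c,
        cell_centers=np.array(centers),
        cell_radius=cell_radius,
        params=params,
        seed=0,
    )


def random_3d(
    n_cells: int = 25,
    seed: int = 0,
    params: ModelParams | None = None,
    cell_radius: float = 10.0,
) -> Scenario:
    """Random layout in the 3D box with a central capillary along axis 1."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    params = params or ModelParams()
    from dataclasses import replace as _rep

    params = _rep(params, phase=_rep(params.phase, eps=EPS_3D))
    grid = Grid(
        (int(BOX_3D[0] / H_3D), int(BOX_3D[1] / H_3D), int(BOX_3D[2] / H_3D)),
        H_3D,
    )
    R_cap = 2.0 * params.tip.R_c
    d = params.hypoxia.d_oxygen
    rng = np.random.default_rng(seed)
    ext = np.asarray(grid.extents)
    axis_point = np.array([ext[0] / 2.0, 0.0, ext[2] / 2.0])  # cylinder axis

    def far_from_capillary(p: np.ndarray) -> bool:
        rho = np.hypot(p[0] - axis_point[0], p[2] - axis_point[2])
        return rho > R_cap + d

    lo = np.full(3, cell_radius)
    hi = ext - cell_radius
    centers = _reject_sample(rng, n_cells, lo, hi, 2.0 * cell_radius, far_from_capillary)
    return Scenario(
        name=f"random_3d_n{n_cells}_s{seed}",
        grid=grid,
        vessel_kind="central_cylinder",
        vessel_size=R_cap,
        cell_centers=centers,
        cell_radius=cell_radius,
        params=params,
        seed=seed,
    )


def _initial_phi(sc: Scenario) -> ScalarField:
    grid = sc.grid
    eps = sc.params.phase.eps
    axes = [grid.node_coords(a) for a in range(grid.dims)]
    mesh = np.meshgrid(*axes, indexing="ij")
    if sc.vessel_kind == "bottom_stripe":
        H = grid.extents[0]
        signed = mesh[0] - (H - sc.vessel_size)  # positive inside the stripe
    elif sc.vessel_kind == "central_cylinder":
        c0 = grid.extents[0] / 2.0
        c2 = grid.extents[2] / 2.0
        rho = np.sqrt((mesh[0] - c0) ** 2 + (mesh[2] - c2) ** 2)
        signed = sc.vessel_size - rho
    else:
        raise ValueError(f"unknown vessel kind {sc.vessel_kind!r}")
    return ScalarField(grid, np.tanh(signed / (np.sqrt(2.0) * eps)), "phi")


def capillary_ends(sc: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """Physical end points of the parent capillary (flow inlet / outlet)."""
    ext = np.asarray(sc.grid.extents)
    if sc.vessel_kind == "bottom_stripe":
        y = ext[0] - sc.vessel_size / 2.0
        return np.array([y, 0.0]), np.array([y, ext[1]])
    c0 = ext[0] / 2.0
    c2 = ext[2] / 2.0
    return np.array([c0, 0.0, c2]), np.array([c0, ext[1], c2])


def build_state(sc: Scenario) -> SimulationState:
    """Materialise a scenario into a steppable simulation state.

    Asserts the placement constraints (cells pairwise non-overlapping and
    clear of the capillary) before building the fields.
    """
    centers = sc.cell_centers
    if len(centers) > 1:
        diffs = centers[:, None, :] - centers[None, :, :]
        dists = np.linalg.norm(diffs, axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() < 2.0 * sc.cell_radius - 1e-9:
            raise ValueError("tissue cells overlap")
    phi = _initial_phi(sc)
    for c in centers:
        idx = tuple(np.clip(sc.grid.position_to_index(c).round().astype(int),
                            0, np.asarray(sc.grid.shape) - 1))
        if phi.values[idx] > 0:
            raise ValueError("tissue cell overlaps the initial vessel")
    psi = build_psi(sc.grid, centers, sc.cell_radius, sc.params.phase.eps)
    T = ScalarField.full(sc.grid, 0.0, "T")
    cells = [
        TissueCell(id=i, center=c, radius=sc.cell_radius)
        for i, c in enumerate(centers)
    ]
    state = SimulationState(
        grid=sc.grid,
        phi=phi,
        psi=psi,
        T=T,
        params=sc.params,
        cells=cells,
        capillary_ends=capillary_ends(sc),
        seed=sc.seed,
    )
    return state
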
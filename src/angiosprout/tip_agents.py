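"""Discrete endothelial tip-cell agents.

Tip cells are point agents of radius ``R_c`` that nucleate on the vessel
wall wherever the angiogenic factor is high enough (T >= T_c), its
gradient steep enough (|grad T| >= G_m) and no other active tip sits
within ``4 * R_c`` — a lateral-inhibition exclusion that reproduces the
"salt and pepper" tip/stalk pattern without modelling Delta-Notch
signalling explicitly.

An active tip migrates chemotactically, v = chi * grad T, with the speed
capped at ``chi * G_M`` once the gradient modulus exceeds ``G_M``.  Tips
cannot enter tissue cells: close to a cell the inward radial velocity
component is removed and the tip slides tangentially around it.  As a tip
moves it imprints vessel phase (phi) in a disc of radius R_c around its
centre, extending the sprout; the imprinted level depends on tip speed and
on the local proliferation rate.

A tip is retired when it merges into vessel that is not its own recent
trail — another sprout, the parent capillary, or its own older sprout
after looping (all anastomoses; detected on an ownership grid recording
which agent laid down each vessel node, plus a short trailing-position
memory) — or when it sits in a flat gradient (|grad T| < G_m / 2) for a
sustained window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_fields import gradient_field, interp_at
from .endothelial_phase import proliferation_rate

__all__ = [
    "TipParams",
    "TipCell",
    "activate_candidates",
    "tip_velocity",
    "avoid_tissue_cells",
    "move_and_imprint",
    "agent_update",
]

# owner-grid sentinels: vessel laid down by no agent (initial capillary) and
# "not vessel yet"
OWNER_INITIAL = -1
OWNER_NONE = -2


@dataclass
class TipParams:
    """Tip-cell agent parameters.

    R_c : tip-cell radius (um).
    T_c : minimum factor concentration for activation (units of T_s).
        The factor diffuses slowly and vessels absorb it, so the wall
        band sees T above this threshold only where a hypoxic cell's
        concentration halo has reached the vessel; tip nucleation is
        thereby confined to source-adjacent wall, which is what
        localises branching to hypoxic regions.
    G_m : minimum gradient modulus for activation (T_s / um).
    G_M : gradient modulus at which the migration speed saturates.
    chi : chemotactic coefficient (um^2 / s per unit of T); the maximum tip
        speed is chi * G_M.
    chi_variant : "constant", or "hypoxia_scaled" for chi0 * (1 - T) with
        the local concentration as hypoxia proxy (clipped at zero).
    wall_band : |phi| threshold defining the vessel-wall band scanned for
        activation candidates.
    stall_window : seconds of sustained flat gradient before a tip retires.
    """

    R_c: float = 5.0
    T_c: float = 0.04
    G_m: float = 2.0e-3
    G_M: float = 2.0e-2
    chi: float = 0.3125
    chi_variant: str = "constant"
    wall_band: float = 0.9
    stall_window: float = 1800.0

    def __post_init__(self) -> None:
        for name in ("R_c", "T_c", "G_m", "G_M", "chi"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TipParams.{name} must be strictly positive")
        if self.G_m > self.G_M:
            raise ValueError("TipParams requires G_m <= G_M")
        if self.chi_variant not in ("constant", "hypoxia_scaled"):
            raise ValueError(f"unknown chi_variant {self.chi_variant!r}")

    @property
    def max_speed(self) -> float:
        """Saturated migration speed chi * G_M (um/s)."""
        return self.chi * self.G_M

    @classmethod
    def from_max_speed(cls, v_max_um_per_min: float, **kw) -> "TipParams":
        """Build params from the maximum tip speed quoted in um/min."""
        tmp = cls(**kw)
        chi = (v_max_um_per_min / 60.0) / tmp.G_M
        kw["chi"] = chi
        return cls(**kw)


@dataclass
class TipCell:
    """A migrating tip-cell agent (positions in um, velocity in um/s)."""

    id: int
    position: np.ndarray
    velocity: np.ndarray
    birth_time: float
    active: bool = True
    birth_position: np.ndarray = field(default=None)  # type: ignore[assignment]
    path_length: float = 0.0
    low_grad_time: float = 0.0
    trail: list = field(default_factory=list)  # subsampled past positions

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.birth_position is None:
            self.birth_position = self.position.copy()


def tip_velocity(gradT: np.ndarray, T_local: float, params: TipParams) -> np.ndarray:
    """Chemotactic velocity: chi_eff * grad T, speed-capped at chi_eff * G_M."""
    gradT = np.asarray(gradT, dtype=float)
    if params.chi_variant == "hypoxia_scaled":
        chi_eff = params.chi * max(0.0, 1.0 - float(T_local))
    else:
        chi_eff = params.chi
    g = float(np.linalg.norm(gradT))
    if g == 0.0 or chi_eff == 0.0:
        return np.zeros_like(gradT)
    if g < params.G_M:
        return chi_eff * gradT
    return chi_eff * params.G_M * gradT / g


def avoid_tissue_cells(
    v: np.ndarray, tip_pos: np.ndarray, cells, R_c: float
) -> np.ndarray:
    """Contour tissue cells: drop the inward radial velocity component.

    For every tissue cell whose surface lies closer than ``2 * R_c`` to
    the tip centre, the component of ``v`` along the centre-to-tip radial
    direction is removed when it points toward the cell, leaving a purely
    tangential (azimuthal) motion.  Violating cells are processed in index
    order.  ``cells`` may be a list of cells or a precomputed
    ``(centers, radii)`` array pair.
    """
    v = np.asarray(v, dtype=float).copy()
    tip_pos = np.asarray(tip_pos, dtype=float)
    if isinstance(cells, tuple):
        centers, radii = cells
    else:
        centers = np.array([c.center for c in cells], dtype=float)
        radii = np.array([c.radius for c in cells], dtype=float)
    if len(centers) == 0:
        return v
    rvecs = tip_pos - centers
    dists = np.linalg.norm(rvecs, axis=1)
    near = np.nonzero(dists - radii < 2.0 * R_c)[0]
    for i in near:  # index order; usually zero or one violating cell
        dist = dists[i]
        if dist == 0.0:
            # degenerate: tip exactly at the cell centre; leave v unchanged
            continue
        rhat = rvecs[i] / dist
        radial = float(v @ rhat)
        if radial < 0.0:
            v -= radial * rhat
    return v


def _tip_phi_level(speed: float, alpha_p_local: float, params, phase) -> float:
    """Imprinted phi inside a tip: grows with speed and local proliferation.

    Calibrated so that a tip at the saturation speed imprints phi = 1
    regardless of the proliferation contribution.
    """
    c_v = 1.0 / params.max_speed
    c_p = 0.5 / phase.max_proliferation
    return min(1.0, c_v * speed + c_p * alpha_p_local)


def _ball_indices(grid, center: np.ndarray, radius: float):
    from .angiogenic_factor import source_node_indices

    return source_node_indices(grid, center, radius)


def activate_candidates(state) -> list[TipCell]:
    """Scan the vessel wall and nucleate new tip cells.

    A wall node (|phi| < wall_band) becomes a tip iff T >= T_c,
    |grad T| >= G_m, and it lies farther than 4*R_c from every active tip
    and from every tip accepted earlier in the same raster-order scan.
    The accepted tips are appended to ``state.tips`` and returned.
    """
    params = state.params.tip
    grid = state.grid
    gcomps = gradient_field(state.T)
    gmag = np.sqrt(sum(c * c for c in gcomps))
    cond = (
        (np.abs(state.phi.values) < params.wall_band)
        & (state.T.values >= params.T_c)
        & (gmag >= params.G_m)
    )
    if not cond.any():
        return []
    idx = np.argwhere(cond)  # raster order
    positions = (idx + 0.5) * grid.h
    occupied = [t.position for t in state.tips if t.active]
    min_sep = 4.0 * params.R_c
    if occupied:
        occ = np.asarray(occupied)
        d = np.linalg.norm(positions[:, None, :] - occ[None, :, :], axis=-1)
        keep = (d > min_sep).all(axis=1)
        positions = positions[keep]
    new: list[TipCell] = []
    for p in positions:
        if any(np.linalg.norm(p - t.position) <= min_sep for t in new):
            continue
        tip = TipCell(
            id=state.next_tip_id(),
            position=p,
            velocity=np.zeros(grid.dims),
            birth_time=state.t,
        )
        new.append(tip)
        state.log_tip_event("activate", tip)
    state.tips.extend(new)
    return new


def _check_merge(state, tip: TipCell) -> int | None:
    """Owner id of a vessel the tip has fused with, or None.

    Fires when the tip disc overlaps vessel core (phi > 0.3) that is not
    its own *recent* trail: another agent's sprout or the parent capillary
    (a cross-anastomosis), or its own older sprout after closing a loop
    (a self-anastomosis).  Only fires after the tip has travelled more
    than 4*R_c, and ignores vessel near its birth site (the parent wall
    it budded from).
    """
    params = state.params.tip
    if tip.path_length <= 4.0 * params.R_c:
        return None
    grid = state.grid
    idx = _ball_indices(grid, tip.position, params.R_c)
    if len(idx[0]) == 0:
        return None
    phi_here = state.phi.values[idx]
    owner_here = state.owner[idx]
    coords = np.stack([(i + 0.5) * grid.h for i in idx], axis=-1)
    far_from_birth = (
        np.linalg.norm(coords - tip.birth_position, axis=-1) > 2.0 * params.R_c
    )
    vessel = (phi_here > 0.3) & (owner_here != OWNER_NONE) & far_from_birth
    if not vessel.any():
        return None
    foreign = vessel & (owner_here != tip.id)
    if foreign.any():
        owners, counts = np.unique(owner_here[foreign], return_counts=True)
        return int(owners[np.argmax(counts)])
    # own vessel beyond the recent trail window = a closed loop
    own = vessel & (owner_here == tip.id)
    if own.any() and tip.trail:
        recent = np.asarray(tip.trail[-_RECENT_TRAIL_POINTS:])
        d = np.linalg.norm(coords[own][:, None, :] - recent[None], axis=-1)
        if (d.min(axis=1) > 2.0 * params.R_c).any():
            return int(tip.id)
    return None


# trail subsampling: one point per R_c/2 of travel; the "recent" window the
# tip may freely touch covers the last ~4*R_c of its path
_TRAIL_SPACING_FACTOR = 0.5
_RECENT_TRAIL_POINTS = 9


def move_and_imprint(state, dt: float):
    """Advance every active tip by ``dt`` seconds and imprint the sprout.

    Order per tip: chemotactic velocity -> tissue-cell avoidance -> move
    (clamped to the box) -> merge / stall bookkeeping -> phi imprint of
    a disc of radius R_c.  Mutates ``state`` in place and returns it.
    """
    params = state.params.tip
    phase = state.params.phase
    grid = state.grid
    active = [t for t in state.tips if t.active]
    if not active:
        return state
    gcomps = gradient_field(state.T)
    coords = np.array([t.position for t in active]).T / grid.h - 0.5
    from scipy.ndimage import map_coordinates

    grads = np.stack(
        [map_coordinates(c, coords, order=1, mode="nearest") for c in gcomps],
        axis=-1,
    )
    T_locs = map_coordinates(state.T.values, coords, order=1, mode="nearest")
    cell_arrays = (
        np.array([c.center for c in state.cells], dtype=float).reshape(-1, grid.dims),
        np.array([c.radius for c in state.cells], dtype=float),
    )
    for k, tip in enumerate(active):
        gradT = grads[k]
        T_loc = T_locs[k]
        v = tip_velocity(gradT, T_loc, params)
        v = avoid_tissue_cells(v, tip.position, cell_arrays, params.R_c)
        tip.velocity = v
        step_vec = v * dt
        new_pos = grid.clamp(tip.position + step_vec)
        tip.path_length += float(np.linalg.norm(new_pos - tip.position))
        tip.position = new_pos

        # trail memory for self-anastomosis detection
        spacing = _TRAIL_SPACING_FACTOR * params.R_c
        if not tip.trail or (
            np.linalg.norm(tip.position - tip.trail[-1]) >= spacing
        ):
            tip.trail.append(tip.position.copy())

        # stall bookkeeping on the raw gradient (pre-avoidance)
        if float(np.linalg.norm(gradT)) < params.G_m / 2.0:
            tip.low_grad_time += dt
        else:
            tip.low_grad_time = 0.0

        target = _check_merge(state, tip)
        if target is not None:
            tip.active = False
            state.log_tip_event("merge", tip, target=target)
            if target == OWNER_INITIAL:
                state.counters["capillary_merges"] += 1
            state.counters["merges"] += 1
        elif tip.low_grad_time >= params.stall_window:
            tip.active = False
            state.log_tip_event("deactivate", tip)

        # imprint the tip disc (also for the final position of a merging tip,
        # so the fusion is materialised in phi)
        alpha_loc = proliferation_rate(float(T_loc), phase)
        level = _tip_phi_level(float(np.linalg.norm(v)), alpha_loc, params, phase)
        idx = _ball_indices(grid, tip.position, params.R_c)
        if len(idx[0]):
            # never lay vessel into the tissue-cell boundary ramp or interior
            # (psi >= -0.5): the overlap penalty would expel it anyway, and
            # keeping the disc on the outer ramp keeps phi = +1 linearly
            # stable everywhere vessel actually sits
            keep = state.psi.values[idx] < -0.5
            idx = tuple(i[keep] for i in idx)
        if len(idx[0]):
            newly = state.phi.values[idx] <= 0.0
            state.phi.values[idx] = np.maximum(state.phi.values[idx], level)
            own = state.owner[idx]
            own[newly] = tip.id
            state.owner[idx] = own
    return state


def agent_update(state, dt: float):
    """One agent cadence step: activation scan, then migration + imprint."""
    activate_candidates(state)
    return move_and_imprint(state, dt)
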
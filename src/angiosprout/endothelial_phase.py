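"""Conservative interface dynamics of the vessel order parameter ``phi``.

The vessel network is described by an order parameter ``phi`` that is +1
inside endothelial tissue and -1 outside, evolving under conserved
(Cahn-Hilliard type) dynamics driven by a chemical potential

    mu = phi**3 - phi - eps**2 * lap(phi)
         + gamma * (phi**2 - 1) * (psi - 2) * (psi + 1)**2

plus a local proliferation source alpha_p(T) * phi * Theta(phi) that adds
vessel mass wherever endothelial cells see angiogenic factor.  The
``gamma`` term is an energy penalty for overlap between vessels and the
static tissue-cell field ``psi`` (+1 inside tissue cells); it vanishes
wherever ``psi = -1``.

Proliferation is linear in the factor concentration ``T`` up to a
saturation concentration ``T_p``: alpha_p = beta_p * min(T, T_p).

Time integration is explicit Euler.  The interface term is fourth order in
space, so the stable step scales like h**4 / (M * eps**2); see
:func:`stable_dt_phi`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_fields import Grid, ScalarField, laplacian_array

__all__ = [
    "PhaseParams",
    "chemical_potential",
    "proliferation_rate",
    "step_phi",
    "stable_dt_phi",
    "build_psi",
    "overlap_fraction",
]


@dataclass
class PhaseParams:
    """Parameters of the vessel-phase dynamics.

    M : interface mobility (um^2/s).
    eps : capillary wall width (um); must be >= grid spacing.
    gamma : vessel/tissue-cell overlap penalty (dimensionless).  Set high
        enough that the positive domains of phi and psi barely overlap,
        but below 1/2: the penalty makes the vessel phase (phi = +1)
        linearly unstable wherever gamma * |(psi-2)(psi+1)^2| > 1, which
        with gamma in (1/4, 1/2) happens strictly inside tissue cells
        (expelling invading vessel) while phi = +1 remains stable at and
        outside the cell surface.  Larger gamma widens the unstable band
        into the smoothed cell boundary and vessel mass piles up there
        without bound.
    beta_p : proliferation coefficient (1/s per unit of T, with T measured
        in units of the source concentration T_s).
    T_p : factor concentration at which proliferation saturates, so the
        maximum proliferation rate is beta_p * T_p.
    """

    M: float = 0.05
    eps: float = 3.75
    gamma: float = 0.4
    beta_p: float = 3.5e-4
    T_p: float = 0.8

    def __post_init__(self) -> None:
        for name in ("M", "eps", "gamma", "beta_p", "T_p"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PhaseParams.{name} must be strictly positive")

    @property
    def max_proliferation(self) -> float:
        """Saturated proliferation rate beta_p * T_p (1/s)."""
        return self.beta_p * self.T_p


def proliferation_rate(T, params: PhaseParams):
    """Proliferation rate alpha_p(T) = beta_p * min(T, T_p).

    Continuous, nondecreasing and bounded by beta_p * T_p.  Small negative
    T (numerical undershoot) is clamped to zero.
    """
    T = np.clip(np.asarray(T, dtype=float), 0.0, params.T_p)
    out = params.beta_p * T
    return float(out) if out.ndim == 0 else out


def psi_coupling(psi: ScalarField, params: PhaseParams) -> np.ndarray:
    """The static factor gamma * (psi - 2) * (psi + 1)**2 of the penalty."""
    s = psi.values
    return params.gamma * (s - 2.0) * (s + 1.0) ** 2


def chemical_potential(
    phi: ScalarField, psi: ScalarField, params: PhaseParams, coupling=None
) -> ScalarField:
    """Chemical potential mu of the conserved interface dynamics.

    ``coupling`` may pass a precomputed :func:`psi_coupling` array (psi is
    static, so steppers cache it).
    """
    if phi.grid != psi.grid:
        raise ValueError("phi and psi must share a grid")
    p = phi.values
    if coupling is None:
        coupling = psi_coupling(psi, params)
    p2 = p * p
    mu = p2 * p - p
    mu -= params.eps**2 * laplacian_array(p, phi.grid.h)
    mu += (p2 - 1.0) * coupling
    return ScalarField(phi.grid, mu, "mu")


def step_phi(state, dt: float):
    """Advance phi by one explicit Euler step of length ``dt`` seconds.

    d(phi)/dt = M * lap(mu) + alpha_p(T) * phi * Theta(phi), with
    Theta(0) = 0 so proliferation acts strictly inside the vessel.  The
    interface term is in conservative form, so with beta_p = 0 the total
    integral of phi is preserved to round-off.  Mutates ``state`` in place
    and returns it.
    """
    params = state.params.phase
    coupling = getattr(state, "psi_coupling_cache", None)
    if coupling is None:
        coupling = psi_coupling(state.psi, params)
        try:
            state.psi_coupling_cache = coupling
        except AttributeError:  # plain objects in tests
            pass
    mu = chemical_potential(state.phi, state.psi, params, coupling=coupling)
    dphi = params.M * laplacian_array(mu.values, state.grid.h)
    pv = state.phi.values
    inside = pv > 0.0
    if params.beta_p > 0.0 and inside.any():
        alpha = proliferation_rate(state.T.values, params)
        dphi += np.where(inside, alpha * pv, 0.0)
    pv += dt * dphi
    if not np.isfinite(pv).all():
        raise FloatingPointError(
            f"phi became non-finite at t={state.t:.1f}s: unstable dt={dt}"
        )
    return state


def stable_dt_phi(grid: Grid, params: PhaseParams, safety: float = 0.5) -> float:
    """Largest safe explicit step for the phi dynamics, times ``safety``.

    Von Neumann analysis on the discrete Laplacian symbol
    s_max = 4*dims/h**2: the biharmonic part contributes
    M*eps**2*s_max**2; the bulk part d/dphi(phi**3 - phi) at most
    2*M*s_max; and the overlap penalty, whose phi-derivative
    2*phi*(psi - 2)*(psi + 1)**2 reaches ~8.8*gamma inside tissue cells
    (|phi| <= 1.1, |(psi-2)(psi+1)**2| <= 4), another
    8.8*gamma*M*s_max.  dt_max = 2 over the sum.
    """
    s_max = 4.0 * grid.dims / grid.h**2
    coeff = params.M * (
        params.eps**2 * s_max**2 + (2.0 + 8.8 * params.gamma) * s_max
    )
    return safety * 2.0 / coeff


def build_psi(grid: Grid, centers: np.ndarray, radius: float, eps: float) -> ScalarField:
    """Static tissue-cell field: +1 inside each sphere, -1 outside.

    The indicator is smoothed with a tanh ramp of width ``eps`` across each
    cell surface (union over cells via the nearest-surface signed
    distance), which avoids staircase artifacts in the gamma coupling.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        return ScalarField.full(grid, -1.0, "psi")
    axes = np.meshgrid(*[grid.node_coords(a) for a in range(grid.dims)], indexing="ij")
    pos = np.stack(axes, axis=-1)  # (*shape, dims)
    dmin = np.full(grid.shape, np.inf)
    for c in centers:
        d = np.linalg.norm(pos - c, axis=-1)
        np.minimum(dmin, d, out=dmin)
    signed = radius - dmin  # positive inside a cell
    return ScalarField(grid, np.tanh(signed / (np.sqrt(2.0) * eps)), "psi")


def overlap_fraction(phi: ScalarField, psi: ScalarField) -> float:
    """Fraction of the tissue-cell volume also occupied by vessel.

    integral(Theta(phi)*Theta(psi)) / integral(Theta(psi)); the gamma
    penalty is supposed to keep this small (a percent or so).
    """
    inside_cells = psi.values > 0.0
    denom = inside_cells.sum()
    if denom == 0:
        return 0.0
    return float((phi.values > 0.0)[inside_cells].sum() / denom)
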
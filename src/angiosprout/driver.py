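"""Orchestration: full simulations and parameter sweeps.

The stepping loop advances the stiff PDE pair (phi, T) with an explicit
Euler step at the stability-limited dt, updates the (much slower) tip
agents every ``agent_every`` PDE steps, and recomputes the expensive
irrigation machinery -- medial-line skeleton, Poiseuille flow and the
hypoxia rule -- every ``irrigation_interval`` seconds of simulated time.
A run halts when every tissue cell has been irrigated (the network has
grown enough to silence all VEGF sources) or at ``t_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_fields import integrate
from .endothelial_phase import stable_dt_phi, step_phi, overlap_fraction
from .angiogenic_factor import stable_dt_T, step_T, apply_sources
from .tip_agents import agent_update
from .hypoxia_control import update_hypoxia
from .vessel_network import (
    VesselGraph,
    anastomosis_density,
    branch_density,
    mean_diameter,
    skeletonize,
)
from .blood_flow import FlowSolution, pick_inlet_outlet, solve_flow
from .scenarios import Scenario, build_state, random_2d, random_3d
from .state import SimulationState

__all__ = [
    "SimulationResult",
    "SweepSpec",
    "run_simulation",
    "run_sweep",
    "summarize_sweep",
    "compute_descriptors",
]


@dataclass
class SimulationResult:
    """Final state plus the derived network, flow and morphometrics."""

    state: SimulationState
    graph: VesselGraph
    flow: FlowSolution | None
    descriptors: dict
    t_end: float
    all_irrigated: bool
    history: list = field(default_factory=list)


def domain_measure_mm(grid) -> float:
    """Domain area in mm^2 (2D) or volume in mm^3 (3D)."""
    return grid.measure * (1.0e-3) ** grid.dims


def compute_descriptors(state: SimulationState, graph: VesselGraph) -> dict:
    """Branch density, anastomosis density (per mm^d) and mean diameter (um)."""
    measure = domain_measure_mm(state.grid)
    d = {
        "branch_density": branch_density(graph, measure),
        "anastomosis_density": anastomosis_density(graph, measure),
        "n_edges": graph.n_edges,
        "cycle_rank": graph.cycle_rank,
        "capillary_merges": state.counters["capillary_merges"],
        "merges": state.counters["merges"],
    }
    d["mean_diameter"] = (
        mean_diameter(state.phi, graph) if graph.n_edges else float("nan")
    )
    return d


def _irrigation_update(state: SimulationState):
    """Skeletonise, solve flow (Rule 1), apply the hypoxia rule."""
    graph = skeletonize(state.phi, R_c=state.params.tip.R_c)
    flow = None
    if state.params.hypoxia.rule == 1:
        if graph.n_edges == 0:
            return graph, None
        inlet, outlet = pick_inlet_outlet(graph, *state.capillary_ends)
        flow = solve_flow(
            graph, inlet, outlet, Q_min_rel=state.params.hypoxia.Q_min_rel
        )
        update_hypoxia(state, graph=graph, flow=flow)
    else:
        update_hypoxia(state)
    return graph, flow


def run_simulation(
    scenario: Scenario | None = None,
    t_max: float = 86400.0,
    state: SimulationState | None = None,
    record_history: bool = True,
    check_invariants: bool = False,
) -> SimulationResult:
    """Run (or resume) one simulation to irrigation or ``t_max`` seconds.

    Pass either a scenario or an existing (checkpointed) state.  With
    ``check_invariants`` the tip speed cap, the 4*R_c activation
    exclusion, phi boundedness and the vessel/tissue-cell overlap bound
    are asserted at every agent step.
    """
    if state is None:
        if scenario is None:
            raise ValueError("need a scenario or a state")
        state = build_state(scenario)
    params = state.params
    dt = params.dt or min(
        stable_dt_phi(state.grid, params.phase), stable_dt_T(state.grid, params.factor)
    )
    apply_sources(state.T, state.active_source_nodes(), params.factor.T_s)
    graph: VesselGraph = skeletonize(state.phi, R_c=params.tip.R_c)
    flow: FlowSolution | None = None
    history: list = []
    next_irrigation = (
        np.floor(state.t / params.irrigation_interval) + 1
    ) * params.irrigation_interval
    while state.t < t_max:
        step_phi(state, dt)
        step_T(state, dt)
        state.t += dt
        state.step_count += 1
        if state.step_count % params.agent_every == 0:
            agent_update(state, dt * params.agent_every)
            if check_invariants:
                _assert_invariants(state)
        if state.t >= next_irrigation:
            next_irrigation += params.irrigation_interval
            graph, flow = _irrigation_update(state)
            if record_history:
                history.append(
                    {
                        "t_min": state.t / 60.0,
                        "n_hypoxic": state.n_hypoxic,
                        "n_active_tips": len(state.active_tips),
                        "n_edges": graph.n_edges,
                        "cycle_rank": graph.cycle_rank,
                        "phi_mass": integrate(state.phi),
                    }
                )
            if state.all_irrigated:
                break
    # final analysis pass (always with a flow solve for reporting)
    graph = skeletonize(state.phi, R_c=params.tip.R_c)
    if graph.n_edges:
        inlet, outlet = pick_inlet_outlet(graph, *state.capillary_ends)
        flow = solve_flow(graph, inlet, outlet, Q_min_rel=params.hypoxia.Q_min_rel)
    return SimulationResult(
        state=state,
        graph=graph,
        flow=flow,
        descriptors=compute_descriptors(state, graph),
        t_end=state.t,
        all_irrigated=state.all_irrigated,
        history=history,
    )


def _assert_invariants(state: SimulationState) -> None:
    """Agent-layer invariants, asserted after every agent step.

    (i) no tip moves faster than the chemotactic cap chi * G_M;
    (ii) every tip activated at this instant is farther than 4 * R_c from
    every other currently active tip (lateral-inhibition exclusion).
    """
    params = state.params.tip
    cap = params.max_speed * (1.0 + 1e-12)
    for tip in state.active_tips:
        speed = float(np.linalg.norm(tip.velocity))
        if speed > cap:
            raise AssertionError(f"tip {tip.id} exceeds speed cap: {speed}")
    newly = [t for t in state.active_tips if t.birth_time == state.t]
    others = [t for t in state.active_tips if t.birth_time != state.t]
    min_sep = 4.0 * params.R_c
    for tnew in newly:
        for tother in others + [t for t in newly if t.id != tnew.id]:
            # both tips sit where they were at the activation instant
            ref = (
                tother.birth_position
                if tother.birth_time == state.t
                else tother.position
            )
            if float(np.linalg.norm(tnew.birth_position - ref)) <= min_sep:
                raise AssertionError(
                    f"tips {tnew.id}/{tother.id} violate the 4R_c exclusion"
                )


@dataclass
class SweepSpec:
    """A parameter sweep: which knob, which values, which rules, how often.

    parameter : "max_proliferation" (beta_p * T_p, 1/s) or
        "max_tip_speed" (chi * G_M, um/min); only beta_p / chi is varied.
    values : nonempty list of parameter values.
    rules : irrigation rules to run (subset of {1, 2}).
    replicates : random hypoxic-cell layouts per condition (>= 1).
    """

    parameter: str
    values: list
    rules: tuple = (1, 2)
    replicates: int = 3
    t_max: float = 86400.0
    n_cells: int = 30
    dims: int = 2
    base_seed: int = 0
    box: float = 375.0  # 2D box side (um)

    def __post_init__(self) -> None:
        if self.parameter not in ("max_proliferation", "max_tip_speed"):
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        if not self.values:
            raise ValueError("sweep needs at least one value")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def run_sweep(spec: SweepSpec, base_params=None) -> pd.DataFrame:
    """Run the sweep and return one row of descriptors per run.

    A replicate that aborts (numerical instability) is recorded as missing
    and the sweep continues.
    """
    from .state import ModelParams

    rows = []
    for value in spec.values:
        for rule in spec.rules:
            for rep in range(spec.replicates):
                seed = spec.base_seed + rep
                params = (base_params or ModelParams()).with_rule(rule)
                if spec.parameter == "max_proliferation":
                    params = params.with_max_proliferation(value)
                else:
                    params = params.with_max_tip_speed(value)
                if spec.dims == 2:
                    sc = random_2d(spec.n_cells, seed=seed, params=params,
                                   box=spec.box)
                else:
                    sc = random_3d(spec.n_cells, seed=seed, params=params)
                row = {
                    "parameter": spec.parameter,
                    "value": value,
                    "rule": rule,
                    "replicate": rep,
                    "seed": seed,
                }
                try:
                    res = run_simulation(sc, t_max=spec.t_max)
                except FloatingPointError as exc:  # pragma: no cover
                    warnings.warn(f"replicate aborted: {exc}", stacklevel=2)
                    row["aborted"] = True
                    rows.append(row)
                    continue
                row.update(res.descriptors)
                row["t_end_min"] = res.t_end / 60.0
                row["all_irrigated"] = res.all_irrigated
                row["aborted"] = False
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of the descriptors per (value, rule)."""
    ok = df[~df.get("aborted", False)] if "aborted" in df else df
    metrics = ["branch_density", "anastomosis_density", "mean_diameter"]
    g = ok.groupby(["parameter", "value", "rule"])[metrics]
    mean = g.mean()
    sem = g.sem().fillna(0.0)
    out = mean.join(sem, rsuffix="_sem").reset_index()
    return out
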
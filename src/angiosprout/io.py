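"""Output writers and checkpointing (HDF5 fields, GraphML graphs, CSV logs)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .grid_fields import Grid, ScalarField
from .state import ModelParams, SimulationState
from .hypoxia_control import TissueCell
from .tip_agents import TipCell
from .vessel_network import VesselGraph

__all__ = [
    "save_fields",
    "save_checkpoint",
    "load_checkpoint",
    "save_graph",
    "save_events",
    "render_png",
    "save_tiff",
]


def save_fields(path, state: SimulationState, group: str | None = None) -> None:
    """Append a snapshot of phi, psi, T under one time-stamped HDF5 group."""
    name = group or f"t_{state.t:012.1f}s"
    with h5py.File(path, "a") as f:
        g = f.require_group(name)
        for fld in (state.phi, state.psi, state.T):
            if fld.name in g:
                del g[fld.name]
            g.create_dataset(fld.name, data=fld.values, compression="gzip")
        g.attrs["t_s"] = state.t
        g.attrs["h_um"] = state.grid.h


def _params_json(params: ModelParams) -> str:
    return json.dumps(
        {
            "phase": asdict(params.phase),
            "factor": asdict(params.factor),
            "tip": asdict(params.tip),
            "hypoxia": asdict(params.hypoxia),
            "cell_radius": params.cell_radius,
            "agent_every": params.agent_every,
            "irrigation_interval": params.irrigation_interval,
            "dt": params.dt,
        }
    )


def save_checkpoint(path, state: SimulationState) -> None:
    """Full resumable snapshot: fields, agents, cells, clock, parameters."""
    with h5py.File(path, "w") as f:
        for fld in (state.phi, state.psi, state.T):
            f.create_dataset(fld.name, data=fld.values, compression="gzip")
        f.create_dataset("owner", data=state.owner, compression="gzip")
        f.attrs["t_s"] = state.t
        f.attrs["h_um"] = state.grid.h
        f.attrs["seed"] = state.seed
        f.attrs["tip_counter"] = state._tip_counter
        f.attrs["step_count"] = state.step_count
        f.attrs["params"] = _params_json(state.params)
        f.attrs["capillary_ends"] = np.asarray(state.capillary_ends)
        f.attrs["counters"] = json.dumps(state.counters)
        cells = state.cells
        f.create_dataset("cell_centers", data=np.array([c.center for c in cells]))
        f.create_dataset("cell_radius", data=np.array([c.radius for c in cells]))
        f.create_dataset("cell_hypoxic", data=np.array([c.hypoxic for c in cells]))
        f.create_dataset(
            "cell_deact_t",
            data=np.array(
                [c.deactivation_time if c.deactivation_time is not None else np.nan
                 for c in cells]
            ),
        )
        tips = state.tips
        if tips:
            f.create_dataset("tip_pos", data=np.array([t.position for t in tips]))
            f.create_dataset("tip_vel", data=np.array([t.velocity for t in tips]))
            f.create_dataset("tip_birth_pos",
                             data=np.array([t.birth_position for t in tips]))
            f.create_dataset(
                "tip_scalar",
                data=np.array(
                    [[t.id, t.birth_time, float(t.active), t.path_length,
                      t.low_grad_time] for t in tips]
                ),
            )


def load_checkpoint(path) -> SimulationState:
    from .endothelial_phase import PhaseParams
    from .angiogenic_factor import FactorParams
    from .tip_agents import TipParams
    from .hypoxia_control import HypoxiaParams

    with h5py.File(path, "r") as f:
        p = json.loads(f.attrs["params"])
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
        phi = np.array(f["phi"])
        grid = Grid(phi.shape, float(f.attrs["h_um"]))
        cells = [
            TissueCell(
                id=i,
                center=np.array(f["cell_centers"][i]),
                radius=float(f["cell_radius"][i]),
                hypoxic=bool(f["cell_hypoxic"][i]),
                deactivation_time=(
                    None if np.isnan(f["cell_deact_t"][i]) else float(f["cell_deact_t"][i])
                ),
            )
            for i in range(len(f["cell_centers"]))
        ]
        tips = []
        if "tip_pos" in f:
            for i in range(len(f["tip_pos"])):
                tid, birth_t, act, plen, lgt = f["tip_scalar"][i]
                tips.append(
                    TipCell(
                        id=int(tid),
                        position=np.array(f["tip_pos"][i]),
                        velocity=np.array(f["tip_vel"][i]),
                        birth_time=float(birth_t),
                        active=bool(act),
                        birth_position=np.array(f["tip_birth_pos"][i]),
                        path_length=float(plen),
                        low_grad_time=float(lgt),
                    )
                )
        ends = np.asarray(f.attrs["capillary_ends"])
        state = SimulationState(
            grid=grid,
            phi=ScalarField(grid, phi, "phi"),
            psi=ScalarField(grid, np.array(f["psi"]), "psi"),
            T=ScalarField(grid, np.array(f["T"]), "T"),
            params=params,
            cells=cells,
            tips=tips,
            t=float(f.attrs["t_s"]),
            owner=np.array(f["owner"]),
            capillary_ends=(ends[0], ends[1]),
            seed=int(f.attrs["seed"]),
            counters=json.loads(f.attrs["counters"]),
            step_count=int(f.attrs.get("step_count", 0)),
            _tip_counter=int(f.attrs["tip_counter"]),
        )
    return state


def save_graph(path, g: VesselGraph, flow=None) -> None:
    """GraphML export (voxel paths dropped) plus a CSV edge table."""
    out = nx.MultiGraph()
    for n, d in g.g.nodes(data=True):
        out.add_node(n, kind=d["kind"], **{
            f"pos{i}": float(x) for i, x in enumerate(d["pos"])
        })
    rows = []
    for u, v, k, d in g.g.edges(keys=True, data=True):
        q = 0.0
        if flow is not None:
            q = flow.flows.get((u, v, k), flow.flows.get((v, u, k), 0.0))
        out.add_edge(u, v, key=k, length=float(d["length"]),
                     radius=float(d["radius"]), flow=float(q))
        rows.append(
            {"u": u, "v": v, "key": k, "length_um": d["length"],
             "radius_um": d["radius"], "flow": q}
        )
    path = Path(path)
    nx.write_graphml(out, path)
    pd.DataFrame(rows).to_csv(path.with_suffix(".edges.csv"), index=False)


def save_events(directory, state: SimulationState) -> None:
    """Tip-event and hypoxia-timeline CSV logs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(state.tip_events).to_csv(directory / "tip_events.csv", index=False)
    pd.DataFrame(state.hypoxia_events).to_csv(
        directory / "hypoxia_timeline.csv", index=False
    )


def render_png(path, state: SimulationState, flow_mask: np.ndarray | None = None) -> None:
    """Quick-look 2D rendering: vessels red, tissue cells blue, factor shading."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if state.grid.dims != 2:
        raise ValueError("render_png is 2D only; use save_tiff for 3D")
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(state.T.values, cmap="Blues", vmin=0, vmax=1, alpha=0.6)
    vessel = np.ma.masked_where(state.phi.values <= 0, state.phi.values)
    ax.imshow(vessel, cmap="Reds", vmin=0, vmax=1)
    cellmask = np.ma.masked_where(state.psi.values <= 0, state.psi.values)
    ax.imshow(cellmask, cmap="Greens", vmin=0, vmax=1, alpha=0.8)
    if flow_mask is not None:
        fm = np.ma.masked_where(~flow_mask, np.ones_like(state.phi.values))
        ax.imshow(fm, cmap="autumn", vmin=0, vmax=1)
    ax.set_title(f"t = {state.t / 60.0:.0f} min")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_tiff(path, state: SimulationState) -> None:
    """3D phi volume as a float32 TIFF stack for external viewers."""
    import tifffile

    tifffile.imwrite(path, state.phi.values.astype(np.float32))
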
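"""Laminar (Hagen-Poiseuille) flow on the extracted vessel graph.

Each branch is a rigid tube of constant effective radius; with constant
viscosity its hydraulic conductance is proportional to r**4 / L (the flow
units are arbitrary -- only the flowing / not-flowing distinction feeds
the irrigation rule).  A unit pressure drop is applied between a single
inlet node and a single outlet node, and node pressures follow from
Kirchhoff's current law on the conductance-weighted graph Laplacian.
Edges in components that do not contain both boundary nodes carry zero
flow by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .vessel_network import VesselGraph

__all__ = ["FlowSolution", "solve_flow", "flowing_segments", "pick_inlet_outlet"]


@dataclass
class FlowSolution:
    """Node pressures, per-edge flow rates and the flowing-edge set."""

    pressures: dict
    flows: dict  # (u, v, key) -> Q, signed u -> v
    Q_min: float
    flowing: set = field(default_factory=set)

    @property
    def max_flow(self) -> float:
        return max((abs(q) for q in self.flows.values()), default=0.0)

    def node_balance(self, g: VesselGraph, node) -> float:
        """Net flow into a node (zero at interior nodes to solver tolerance)."""
        bal = 0.0
        for u, v, k in g.g.edges(node, keys=True):  # u == node here
            if u == v:
                continue
            if (u, v, k) in self.flows:
                bal -= self.flows[(u, v, k)]  # oriented node -> v: outflow
            else:
                bal += self.flows[(v, u, k)]  # oriented v -> node: inflow
        return bal


def _edge_conductance(d: dict, h: float) -> float:
    r = max(float(d.get("radius", h / 2.0)), h / 2.0)
    L = max(float(d["length"]), h)
    return r**4 / L


def solve_flow(
    g: VesselGraph, inlet, outlet, Q_min_rel: float = 1.0e-6
) -> FlowSolution:
    """Solve the unit-pressure-drop Poiseuille network between two nodes.

    Pressures are fixed at 1 (inlet) and 0 (outlet); every other node is a
    Kirchhoff balance.  Self-loops carry no pressure drop and hence zero
    net flow.  Returns all-zero flows (with a warning) if inlet and outlet
    are not connected.
    """
    G = g.g
    if inlet not in G or outlet not in G:
        raise ValueError("inlet/outlet must be nodes of the vessel graph")
    flows = {(u, v, k): 0.0 for u, v, k in G.edges(keys=True)}
    pressures = {n: 0.0 for n in G.nodes}
    comp = nx.node_connected_component(G, inlet)
    if outlet not in comp:
        warnings.warn("inlet and outlet are disconnected: no flow", stacklevel=2)
        return FlowSolution(pressures, flows, 0.0)

    nodes = sorted(comp)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    comp_edges = [
        (u, v, k, d)
        for u, v, k, d in G.edges(keys=True, data=True)
        if u in comp and u != v
    ]
    L = sp.lil_matrix((n, n))
    for u, v, k, d in comp_edges:
        c = _edge_conductance(d, g.grid.h)
        iu, iv = pos[u], pos[v]
        L[iu, iu] += c
        L[iv, iv] += c
        L[iu, iv] -= c
        L[iv, iu] -= c
    b = np.zeros(n)
    p = np.zeros(n)
    fixed = {pos[inlet]: 1.0, pos[outlet]: 0.0}
    free = [i for i in range(n) if i not in fixed]
    L = L.tocsr()
    if free:
        A = L[free][:, free]
        rhs = b[free] - L[free][:, list(fixed)] @ np.array(list(fixed.values()))
        p[free] = spla.spsolve(A.tocsc(), rhs)
    for i, val in fixed.items():
        p[i] = val
    for u, v, k, d in comp_edges:
        c = _edge_conductance(d, g.grid.h)
        flows[(u, v, k)] = c * (p[pos[u]] - p[pos[v]])
    pressures.update({nd: float(p[pos[nd]]) for nd in nodes})
    q_max = max((abs(q) for q in flows.values()), default=0.0)
    Q_min = Q_min_rel * q_max
    fs = FlowSolution(pressures, flows, Q_min)
    fs.flowing = flowing_segments(fs, Q_min)
    return fs


def flowing_segments(fs: FlowSolution, Q_min: float) -> set:
    """Edges carrying flow above the numerical-zero threshold."""
    return {e for e, q in fs.flows.items() if abs(q) > Q_min}


def pick_inlet_outlet(g: VesselGraph, end_a: np.ndarray, end_b: np.ndarray):
    """Graph nodes nearest the two ends of the initial capillary.

    The parent capillary spans the box, and blood enters at one of its
    ends and leaves at the other; sprout loops that fuse back onto it then
    sit on parallel pressure paths and carry flow.
    """
    if g.n_nodes == 0:
        raise ValueError("empty vessel graph")
    nodes = list(g.g.nodes)
    pos = np.array([g.g.nodes[n]["pos"] for n in nodes])
    ia = int(np.argmin(np.linalg.norm(pos - np.asarray(end_a), axis=1)))
    ib = int(np.argmin(np.linalg.norm(pos - np.asarray(end_b), axis=1)))
    if nodes[ia] == nodes[ib] and len(nodes) > 1:
        # degenerate tiny graph: pick the two most separated nodes instead
        d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        ia, ib = np.unravel_index(np.argmax(d), d.shape)
    return nodes[ia], nodes[ib]
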
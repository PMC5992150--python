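"""Aggregate parameter set and the full mutable simulation state."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid_fields import Grid, ScalarField
from .endothelial_phase import PhaseParams
from .angiogenic_factor import FactorParams, source_node_indices
from .tip_agents import TipCell, TipParams, OWNER_INITIAL, OWNER_NONE
from .hypoxia_control import HypoxiaParams, TissueCell

__all__ = ["ModelParams", "SimulationState"]


@dataclass
class ModelParams:
    """Everything the stepping loop needs, grouped by sub-model.

    cell_radius : tissue-cell radius (um).
    agent_every : agent cadence, in PDE steps.
    irrigation_interval : seconds of simulated time between skeleton /
        flow / hypoxia updates.
    dt : PDE step (s); None selects the stability-limited step.
    """

    phase: PhaseParams = field(default_factory=PhaseParams)
    factor: FactorParams = field(default_factory=FactorParams)
    tip: TipParams = field(default_factory=TipParams)
    hypoxia: HypoxiaParams = field(default_factory=HypoxiaParams)
    cell_radius: float = 10.0
    agent_every: int = 10
    irrigation_interval: float = 900.0
    dt: float | None = None

    def with_rule(self, rule: int) -> "ModelParams":
        return replace(self, hypoxia=replace(self.hypoxia, rule=rule))

    def with_max_proliferation(self, rate: float) -> "ModelParams":
        """Set beta_p so that the saturated proliferation rate is ``rate`` (1/s)."""
        return replace(self, phase=replace(self.phase, beta_p=rate / self.phase.T_p))

    def with_max_tip_speed(self, v_um_per_min: float) -> "ModelParams":
        """Set chi so that the saturated tip speed is ``v_um_per_min``."""
        chi = (v_um_per_min / 60.0) / self.tip.G_M
        return replace(self, tip=replace(self.tip, chi=chi))


@dataclass
class SimulationState:
    """Fields + agents + tissue cells + clock; checkpointable."""

    grid: Grid
    phi: ScalarField
    psi: ScalarField
    T: ScalarField
    params: ModelParams
    cells: list[TissueCell]
    tips: list[TipCell] = field(default_factory=list)
    t: float = 0.0
    owner: np.ndarray = None  # type: ignore[assignment]
    capillary_ends: tuple[np.ndarray, np.ndarray] | None = None
    seed: int = 0
    rng: np.random.Generator = None  # type: ignore[assignment]
    counters: dict = field(default_factory=lambda: {"merges": 0, "capillary_merges": 0})
    step_count: int = 0
    tip_events: list = field(default_factory=list)
    hypoxia_events: list = field(default_factory=list)
    _tip_counter: int = 0
    _source_cache: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.owner is None:
            self.owner = np.where(
                self.phi.values > 0.0, OWNER_INITIAL, OWNER_NONE
            ).astype(np.int32)
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    # -- tip bookkeeping -------------------------------------------------
    def next_tip_id(self) -> int:
        i = self._tip_counter
        self._tip_counter += 1
        return i

    @property
    def active_tips(self) -> list[TipCell]:
        return [t for t in self.tips if t.active]

    def log_tip_event(self, kind: str, tip: TipCell, target: int | None = None) -> None:
        self.tip_events.append(
            {
                "t_min": self.t / 60.0,
                "event": kind,
                "tip_id": tip.id,
                "position": tuple(np.round(tip.position, 3)),
                "target": target,
            }
        )

    # -- hypoxic sources -------------------------------------------------
    def active_source_nodes(self):
        """Clamped node index sets of the currently hypoxic cells (cached)."""
        out = []
        r = self.params.factor.source_radius
        for c in self.cells:
            if not c.hypoxic:
                continue
            if c.id not in self._source_cache:
                self._source_cache[c.id] = source_node_indices(self.grid, c.center, r)
            out.append(self._source_cache[c.id])
        return out

    def invalidate_source_cache(self, cell_id: int) -> None:
        self._source_cache.pop(cell_id, None)

    def log_hypoxia_event(self, cell: TissueCell) -> None:
        self.hypoxia_events.append(
            {
                "t_min": self.t / 60.0,
                "cell_id": cell.id,
                "position": tuple(np.round(cell.center, 3)),
                "rule": self.params.hypoxia.rule,
            }
        )

    @property
    def n_hypoxic(self) -> int:
        return sum(1 for c in self.cells if c.hypoxic)

    @property
    def all_irrigated(self) -> bool:
        return self.n_hypoxic == 0
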
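"""Tip-cell agents: activation gates, velocity law, avoidance, imprinting."""

import numpy as np
import pytest

from angiosprout.grid_fields import Grid, ScalarField
from angiosprout.hypoxia_control import TissueCell
from angiosprout.state import ModelParams, SimulationState
from angiosprout.tip_agents import (
    TipCell,
    TipParams,
    activate_candidates,
    agent_update,
    avoid_tissue_cells,
    move_and_imprint,
    tip_velocity,
)


def make_state(grid, phi, T, cells=(), params=None):
    params = params or ModelParams()
    return SimulationState(
        grid=grid,
        phi=ScalarField(grid, phi, "phi"),
        psi=ScalarField.full(grid, -1.0, "psi"),
        T=ScalarField(grid, T, "T"),
        params=params,
        cells=list(cells),
    )


def steep_params():
    """Gates scaled to the shallow lab-bench T ramps used here.

    Same saturated speed as the defaults (0.375 um/min) but G_M low enough
    that a printable linear ramp saturates it.
    """
    from dataclasses import replace

    return replace(
        ModelParams(),
        tip=TipParams(G_m=2.5e-4, G_M=1.0e-3, chi=6.25),
    )


def wall_state(params=None, T_fn=None):
    """A vertical vessel slab with a linear T ramp pulling tips to the right."""
    params = params or steep_params()
    g = Grid((64, 64), 2.5)
    x1 = np.meshgrid(g.node_coords(0), g.node_coords(1), indexing="ij")[1]
    eps = params.phase.eps
    phi = np.tanh((30.0 - x1) / (np.sqrt(2) * eps))  # vessel at left edge
    T = T_fn(x1) if T_fn else 0.3 + 1.5e-3 * x1
    return make_state(g, phi, T, params=params)


class TestTipVelocity:
    def test_zero_gradient_zero_velocity(self):
        p = TipParams()
        assert tip_velocity(np.zeros(2), 0.5, p) == pytest.approx([0, 0])

    def test_linear_regime(self):
        p = TipParams()
        g = np.array([p.G_M / 4, 0.0])
        assert tip_velocity(g, 0.0, p) == pytest.approx(p.chi * g)

    def test_saturation_speed_and_direction(self):
        p = TipParams()
        g = np.array([0.0, 2.0 * p.G_M])
        v = tip_velocity(g, 0.0, p)
        assert np.linalg.norm(v) == pytest.approx(p.chi * p.G_M)
        assert v[1] > 0 and v[0] == 0

    def test_hypoxia_scaled_variant_vanishes_at_full_saturation(self):
        p = TipParams(chi_variant="hypoxia_scaled")
        g = np.array([10 * p.G_M, 0.0])
        assert tip_velocity(g, 1.0, p) == pytest.approx([0, 0])
        # and is reduced, not zero, at intermediate T
        v = tip_velocity(g, 0.5, p)
        assert 0 < np.linalg.norm(v) < p.chi * p.G_M

    def test_speed_cap_holds_for_any_gradient(self):
        p = TipParams()
        rng = np.random.default_rng(11)
        for _ in range(100):
            g = rng.standard_normal(2) * rng.lognormal(0, 3)
            assert np.linalg.norm(tip_velocity(g, 0.0, p)) <= p.max_speed * (1 + 1e-12)


class TestAvoidance:
    def setup_method(self):
        self.cell = TissueCell(id=0, center=np.array([0.0, 0.0]), radius=10.0)

    def test_head_on_velocity_cancelled(self):
        tip = np.array([15.0, 0.0])  # surface distance 5 < 2*R_c
        v = np.array([-1.0, 0.0])
        out = avoid_tissue_cells(v, tip, [self.cell], R_c=5.0)
        assert out == pytest.approx([0.0, 0.0], abs=1e-14)

    def test_45_degree_keeps_tangential_component(self):
        tip = np.array([15.0, 0.0])
        v = np.array([-1.0, 1.0]) / np.sqrt(2)
        out = avoid_tissue_cells(v, tip, [self.cell], R_c=5.0)
        assert out == pytest.approx([0.0, 1.0 / np.sqrt(2)], abs=1e-12)
        assert np.linalg.norm(out) == pytest.approx(np.sqrt(2) / 2, rel=1e-12)

    def test_outward_velocity_unchanged(self):
        tip = np.array([15.0, 0.0])
        v = np.array([1.0, 0.3])
        out = avoid_tissue_cells(v, tip, [self.cell], R_c=5.0)
        assert out == pytest.approx(v)

    def test_far_cell_ignored(self):
        tip = np.array([40.0, 0.0])  # surface distance 30 > 2*R_c
        v = np.array([-1.0, 0.0])
        assert avoid_tissue_cells(v, tip, [self.cell], 5.0) == pytest.approx(v)

    def test_degenerate_tip_at_centre_leaves_v(self):
        v = np.array([0.5, 0.5])
        out = avoid_tissue_cells(v, np.array([0.0, 0.0]), [self.cell], 5.0)
        assert out == pytest.approx(v)


class TestActivation:
    def test_thresholds_met_activates_on_wall(self):
        st = wall_state()
        new = activate_candidates(st)
        assert len(new) > 0
        p = st.params.tip
        for tip in new:
            assert abs(
                st.phi.values[tuple((tip.position / st.grid.h - 0.5).round().astype(int))]
            ) < p.wall_band

    def test_no_factor_no_activation(self):
        st = wall_state(T_fn=lambda x: np.zeros_like(x))
        assert activate_candidates(st) == []

    def test_below_gradient_threshold_no_activation(self):
        # concentration high but flat: gradient gate must block
        st = wall_state(T_fn=lambda x: np.full_like(x, 0.5))
        assert activate_candidates(st) == []

    def test_exclusion_radius_enforced(self):
        st = wall_state()
        new = activate_candidates(st)
        pos = np.array([t.position for t in new])
        if len(pos) > 1:
            d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 4.0 * st.params.tip.R_c

    def test_existing_tip_blocks_neighbourhood(self):
        st = wall_state()
        first = activate_candidates(st)
        # a second scan immediately after must respect the live tips
        second = activate_candidates(st)
        for t2 in second:
            for t1 in first:
                assert np.linalg.norm(t2.position - t1.position) > 4 * st.params.tip.R_c


class TestMoveAndImprint:
    def test_sprout_extends_at_saturation_speed(self):
        params = steep_params()
        st = wall_state(params)
        tip = TipCell(
            id=st.next_tip_id(),
            position=np.array([80.0, 32.0]),
            velocity=np.zeros(2),
            birth_time=0.0,
        )
        st.tips.append(tip)
        dt = 60.0
        n = 40
        for _ in range(n):
            move_and_imprint(st, dt)
        v_max = params.tip.max_speed
        expected = 32.0 + v_max * dt * n
        # the T ramp saturates the gradient, so the tip advances at cap speed
        assert tip.position[1] == pytest.approx(expected, abs=st.grid.h)
        # and the imprinted phi>0 trail reaches the tip
        i0 = int(80.0 / st.grid.h - 0.5)
        trail = st.phi.values[i0] > 0
        assert trail[int(expected / st.grid.h) - 3]

    def test_stalled_tip_deactivates_after_window(self):
        params = steep_params()
        st = make_state(
            Grid((32, 32), 2.5),
            np.full((32, 32), -1.0),
            np.zeros((32, 32)),
            params=params,
        )
        tip = TipCell(0, np.array([40.0, 40.0]), np.zeros(2), 0.0)
        st.tips.append(tip)
        dt = params.tip.stall_window / 4
        for _ in range(5):
            move_and_imprint(st, dt)
        assert not tip.active
        assert any(e["event"] == "deactivate" for e in st.tip_events)

    def test_head_on_tips_anastomose_into_one_component(self):
        from scipy.ndimage import label

        params = steep_params()
        g = Grid((64, 64), 2.5)
        # two seed tips on opposite sides, T peak in the middle pulls them together
        x0, x1 = np.meshgrid(g.node_coords(0), g.node_coords(1), indexing="ij")
        T = 1.0 - np.abs(x1 - 80.0) / 160.0
        st = make_state(g, np.full(g.shape, -1.0), T, params=params)
        a = TipCell(0, np.array([80.0, 20.0]), np.zeros(2), 0.0)
        b = TipCell(1, np.array([80.0, 140.0]), np.zeros(2), 0.0)
        st.tips.extend([a, b])
        for _ in range(200):
            move_and_imprint(st, 60.0)
            if not (a.active or b.active):
                break
        lab, n = label(st.phi.values > 0)
        assert n == 1  # the two sprouts fused
        assert st.counters["merges"] >= 1

    def test_no_trespass_into_tissue_cells(self):
        params = steep_params()
        g = Grid((64, 64), 2.5)
        x0, x1 = np.meshgrid(g.node_coords(0), g.node_coords(1), indexing="ij")
        T = x1 / 160.0  # pull to the right
        cell = TissueCell(id=0, center=np.array([80.0, 100.0]), radius=10.0)
        st = make_state(g, np.full(g.shape, -1.0), T, cells=[cell], params=params)
        tip = TipCell(0, np.array([80.0, 30.0]), np.zeros(2), 0.0)
        st.tips.append(tip)
        for _ in range(400):
            move_and_imprint(st, 30.0)
            assert np.linalg.norm(tip.position - cell.center) >= cell.radius


def test_agent_update_runs_full_cycle():
    st = wall_state()
    agent_update(st, 60.0)
    assert len(st.tips) > 0
    assert all(np.isfinite(t.position).all() for t in st.tips)
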
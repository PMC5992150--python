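"""Vessel-phase dynamics: bulk equilibria, the tanh kink, conservation."""

import numpy as np
import pytest

from angiosprout.grid_fields import Grid, ScalarField, integrate
from angiosprout.endothelial_phase import (
    PhaseParams,
    build_psi,
    chemical_potential,
    proliferation_rate,
    stable_dt_phi,
    step_phi,
)
from angiosprout.angiogenic_factor import FactorParams
from angiosprout.tip_agents import TipParams
from angiosprout.hypoxia_control import HypoxiaParams
from angiosprout.state import ModelParams, SimulationState


def make_state(grid, phi, psi=None, T=0.0, params=None):
    params = params or ModelParams()
    psi = psi if psi is not None else ScalarField.full(grid, -1.0, "psi")
    return SimulationState(
        grid=grid,
        phi=ScalarField(grid, phi, "phi"),
        psi=psi,
        T=ScalarField.full(grid, T, "T"),
        params=params,
        cells=[],
    )


def kink(grid, eps, x0):
    x = np.meshgrid(*[grid.node_coords(a) for a in range(2)], indexing="ij")[0]
    return np.tanh((x - x0) / (np.sqrt(2.0) * eps))


class TestChemicalPotential:
    @pytest.mark.parametrize("phi0,psi0", [(-1.0, -1.0), (1.0, 1.0)])
    def test_bulk_minima_have_zero_potential(self, phi0, psi0):
        g = Grid((16, 16), 1.0)
        mu = chemical_potential(
            ScalarField.full(g, phi0), ScalarField.full(g, psi0), PhaseParams()
        )
        assert np.abs(mu.values).max() == pytest.approx(0.0, abs=1e-14)

    def test_mismatched_grids_rejected(self):
        p = ScalarField.full(Grid((16, 16), 1.0), 0.0)
        q = ScalarField.full(Grid((16, 16), 2.0), 0.0)
        with pytest.raises(ValueError):
            chemical_potential(p, q, PhaseParams())

    def test_tanh_kink_is_stationary_to_h_squared(self):
        # the 1D kink tanh((x-x0)/(sqrt(2) eps)) solves phi^3-phi-eps^2 phi''=0;
        # the discrete residual must shrink as h^2
        eps = 4.0
        params = PhaseParams(eps=eps)
        residuals = []
        for h in (2.0, 1.0, 0.5):
            n = int(128 / h)
            g = Grid((n, 8), h)
            phi = kink(g, eps, 64.0)
            mu = chemical_potential(
                ScalarField(g, phi), ScalarField.full(g, -1.0), params
            )
            interior = mu.values[n // 4 : -n // 4, 2:-2]
            residuals.append(np.abs(interior).max())
        assert residuals[0] / residuals[1] == pytest.approx(4.0, rel=0.3)
        assert residuals[1] / residuals[2] == pytest.approx(4.0, rel=0.3)


class TestProliferationRate:
    def test_piecewise_linear_saturating(self):
        p = PhaseParams(beta_p=2e-3, T_p=0.5)
        assert proliferation_rate(0.0, p) == 0.0
        assert proliferation_rate(0.25, p) == pytest.approx(2e-3 * 0.25)
        assert proliferation_rate(5.0, p) == pytest.approx(2e-3 * 0.5)

    def test_negative_T_clamped(self):
        assert proliferation_rate(-1e-9, PhaseParams()) == 0.0

    def test_monotone_and_continuous_at_threshold(self):
        p = PhaseParams()
        T = np.linspace(0, 2 * p.T_p, 201)
        r = proliferation_rate(T, p)
        assert (np.diff(r) >= -1e-18).all()
        assert proliferation_rate(p.T_p, p) == pytest.approx(p.beta_p * p.T_p)


class TestStepPhi:
    def test_uniform_bulk_is_stationary(self):
        g = Grid((24, 24), 1.0)
        st = make_state(g, np.full(g.shape, -1.0))
        before = st.phi.values.copy()
        step_phi(st, stable_dt_phi(g, st.params.phase))
        assert st.phi.values == pytest.approx(before, abs=1e-14)

    def test_mass_conserved_without_proliferation(self):
        import dataclasses

        g = Grid((32, 32), 2.0)
        rng = np.random.default_rng(7)
        phi = np.tanh(rng.standard_normal(g.shape))
        params = ModelParams(
            phase=dataclasses.replace(PhaseParams(), beta_p=1e-30)
        )
        st = make_state(g, phi, params=params)
        m0 = integrate(st.phi)
        dt = stable_dt_phi(g, st.params.phase)
        for _ in range(200):
            step_phi(st, dt)
        assert integrate(st.phi) == pytest.approx(m0, abs=1e-9 * abs(m0) + 1e-9)

    def test_disc_growth_matches_direct_summation(self):
        # one step of the proliferation term equals dt * sum(alpha_p * phi)+
        g = Grid((64, 64), 1.0)
        x, y = np.meshgrid(g.node_coords(0), g.node_coords(1), indexing="ij")
        disc = np.hypot(x - 32, y - 32) < 20
        phi = np.where(disc, 1.0, -1.0)
        params = ModelParams()
        T_p = params.phase.T_p
        st = make_state(g, phi.copy(), T=T_p, params=params)
        dt = 0.01
        # isolate proliferation: subtract the pure-interface step
        st_interface = make_state(g, phi.copy(), T=0.0, params=params)
        step_phi(st, dt)
        step_phi(st_interface, dt)
        gained = integrate(st.phi) - integrate(st_interface.phi)
        expected = dt * params.phase.max_proliferation * phi[disc].sum() * g.h**2
        assert gained == pytest.approx(expected, rel=1e-6)

    def test_unstable_step_raises(self):
        g = Grid((32, 32), 1.0)
        rng = np.random.default_rng(0)
        st = make_state(g, np.tanh(rng.standard_normal(g.shape)))
        dt_bad = 200.0 * stable_dt_phi(g, st.params.phase)
        with pytest.raises(FloatingPointError):
            for _ in range(200):
                step_phi(st, dt_bad)


class TestBuildPsi:
    def test_levels_inside_and_outside(self):
        g = Grid((40, 40), 1.0)
        psi = build_psi(g, np.array([[20.0, 20.0]]), radius=8.0, eps=2.0)
        assert psi.values[20, 20] > 0.95
        assert psi.values[0, 0] < -0.95

    def test_no_cells_gives_uniform_minus_one(self):
        g = Grid((16, 16), 1.0)
        psi = build_psi(g, np.empty((0, 2)), radius=8.0, eps=2.0)
        assert (psi.values == -1.0).all()
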
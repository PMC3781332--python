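"""Tissue/vessel oxygen solvers against closed-form oracles and
conservation/monotonicity properties."""

import numpy as np
import pytest
from scipy import ndimage

from capatp import (ChamberCondition, NumericsConfig, SimulationState,
                    StabilityError, TransportParams, capillary_step,
                    hill_inverse, make_chamber, run_steady_state, tissue_step)
from capatp.elliptic import o2_balance
from capatp.fixtures import (make_single_capillary_fixture, make_slab_oracle,
                             make_tiny_network)
from capatp.oxygen import (get_coupling, march_vessels_steady,
                           mb_saturation_deriv, sample_wall_po2, stable_dt,
                           kappa_effective)


class TestSlabOracle:
    def test_parabolic_profile(self):
        spec = make_slab_oracle(P0=50.0, L_um=60.0, h_um=2.0)
        res = run_steady_state(spec.geometry, spec.params, spec.chamber)
        z = spec.geometry.grid.axis_coords_um("z")
        num = res.P[2, 2, :]
        ora = spec.oracle(z)
        assert np.max(np.abs(num - ora)) / 50.0 < 0.01

    def test_closed_form_minimum(self):
        # parabola minimum P0 - M0 L^2 / (2 D alpha) at the far face
        spec = make_slab_oracle(P0=50.0, L_um=60.0)
        p = spec.params
        expect = 50.0 - p.M0 * (60e-4) ** 2 / (2 * p.D * p.alpha)
        assert expect == pytest.approx(47.12, abs=0.01)
        assert spec.oracle(60.0) == pytest.approx(expect, rel=1e-12)

    def test_no_consumption_is_flat(self):
        spec = make_slab_oracle(P0=50.0, M0=1e-12, L_um=60.0)
        assert spec.oracle(np.array([0.0, 30.0, 60.0])) == \
            pytest.approx([50.0, 50.0, 50.0], abs=1e-6)

    def test_anoxic_slab_rejected(self):
        from capatp import DomainError
        with pytest.raises(DomainError, match="anoxic"):
            make_slab_oracle(P0=5.0, L_um=400.0)


class TestExplicitTissueStep:
    def _empty_geom(self, params):
        from capatp.geometry import NetworkGeometry, TissueGrid
        return NetworkGeometry(TissueGrid(24.0, 24.0, 24.0, 4.0), [])

    def test_pure_diffusion_equilibrium(self, params):
        p = params.replace(M0=1e-30)
        g = self._empty_geom(p)
        state = SimulationState(P=np.full(g.grid.shape, 30.0),
                                S=np.zeros((0, 50)))
        out = tissue_step(state, g, p, None, dt=stable_dt(g, p))
        np.testing.assert_allclose(out.P, 30.0, rtol=1e-12)

    def test_space_free_consumption_decay(self, params):
        g = self._empty_geom(params)
        P0 = 30.0
        dt = stable_dt(g, params)
        state = SimulationState(P=np.full(g.grid.shape, P0),
                                S=np.zeros((0, 50)))
        out = tissue_step(state, g, params, None, dt)
        m = params.M0 * P0 / (P0 + params.P_cr)
        fac = 1.0 + params.c_Mb / params.alpha * mb_saturation_deriv(P0, params)
        expect = P0 - dt * m / params.alpha / fac
        np.testing.assert_allclose(out.P, expect, rtol=1e-12)

    def test_unstable_dt_raises(self, params):
        g = self._empty_geom(params)
        state = SimulationState(P=np.zeros(g.grid.shape), S=np.zeros((0, 50)))
        state.P[3, 3, 3] = 60.0
        with pytest.raises(StabilityError):
            s = state
            for _ in range(50):
                s = tissue_step(s, g, params, None,
                                dt=2000 * stable_dt(g, params))


class TestVesselCoupling:
    def test_zero_flux_advects_inlet(self, tiny_geom, params):
        # tissue at blood PO2 everywhere -> j = 0 -> S stays at the inlet
        Pb_in = hill_inverse(params.S_in, params)
        state = SimulationState(P=np.full(tiny_geom.grid.shape, Pb_in),
                                S=np.full((tiny_geom.n_vessels, 50),
                                          params.S_in))
        out = capillary_step(state, tiny_geom, params, dt=1e-3)
        np.testing.assert_allclose(out.S, params.S_in, atol=1e-12)
        np.testing.assert_allclose(out.j, 0.0, atol=1e-15)

    def test_steady_march_matches_explicit_fixed_point(self, tiny_geom, params):
        # freeze a nontrivial wall field and march both schemes
        rng_free = np.linspace(20.0, 40.0, 50)[None, :].repeat(
            tiny_geom.n_vessels, axis=0)
        keff = kappa_effective(tiny_geom, params)
        S, Pb, j = march_vessels_steady(rng_free, tiny_geom, params, keff)
        assert np.all((S > 0) & (S < 1))
        # explicit upwind relaxation on the same frozen wall PO2
        coup = get_coupling(tiny_geom)
        dy = tiny_geom.dy_cm
        from capatp.oxygen import _hill_inv_raw, hill_inverse_slope
        Sx = np.full_like(S, params.S_in)
        dt = 0.005  # under the advective CFL of the short fixture
        for _ in range(12000):
            Sc = np.clip(Sx, 1e-12, 1 - 1e-12)
            Pbx = _hill_inv_raw(Sc, params)
            slope = hill_inverse_slope(Sc, params)
            jx = keff[:, None] * (Pbx - rng_free)
            S_prev = np.concatenate(
                [coup.S_in[:, None], Sx[:, :-1]], axis=1)
            adv = -coup.velocity[:, None] * (
                params.C_tilde + params.alpha_b_tilde * slope) \
                * (Sx - S_prev) / dy
            dS = dt * (adv - 2.0 / coup.radius_cm[:, None] * jx) \
                / (params.C + params.alpha_b * slope)
            Sx = Sx + dS
        np.testing.assert_allclose(Sx, S, atol=2e-6)

    def test_discrete_o2_conservation_audit(self, tiny_geom, params):
        """One explicit capillary step satisfies the segment O2 budget."""
        state = SimulationState(P=np.full(tiny_geom.grid.shape, 25.0),
                                S=np.full((tiny_geom.n_vessels, 50), 0.6))
        dt = 1e-3
        out = capillary_step(state, tiny_geom, params, dt)
        coup = get_coupling(tiny_geom)
        dy = tiny_geom.dy_cm
        from capatp.oxygen import _hill_inv_raw, hill_inverse_slope
        Sc = np.clip(state.S, 1e-12, 1 - 1e-12)
        slope = hill_inverse_slope(Sc, params)
        Pw = sample_wall_po2(state.P, coup, tiny_geom.n_vessels, 50)
        keff = kappa_effective(tiny_geom, params)
        j = keff[:, None] * (_hill_inv_raw(Sc, params) - Pw)
        S_prev = np.concatenate([coup.S_in[:, None], state.S[:, :-1]], axis=1)
        R = coup.radius_cm[:, None]
        seg_vol = np.pi * R ** 2 * dy
        lhs = (params.C + params.alpha_b * slope) * (out.S - state.S) * seg_vol
        adv = -coup.velocity[:, None] * (
            params.C_tilde + params.alpha_b_tilde * slope) \
            * (state.S - S_prev) / dy * seg_vol
        wall = j * 2 * np.pi * R * dy
        rhs = dt * (adv - wall)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-8, atol=1e-30)


class TestSteadyStateProperties:
    def test_global_o2_conservation(self, tiny_geom, params, tiny_control):
        bal = o2_balance(tiny_geom, params, tiny_control.chamber,
                         tiny_control.state)
        assert abs(bal["residual"]) < 0.005 * bal["consumption"]

    def test_conservation_with_chamber(self, tiny_geom, params, tiny_control):
        cond = make_chamber("full", 40.0)
        res = run_steady_state(tiny_geom, params, cond,
                               initial=tiny_control.state)
        bal = o2_balance(tiny_geom, params, cond, res.state)
        assert abs(bal["residual"]) < 0.005 * bal["consumption"]

    def test_exit_so2_monotone_in_chamber_po2(self, tiny_geom, params,
                                              tiny_control):
        exits = {}
        for po2 in (15.0, 40.0, 150.0):
            res = run_steady_state(tiny_geom, params,
                                   make_chamber("full", po2),
                                   initial=tiny_control.state)
            exits[po2] = res.S[:, -1]
        assert np.all(exits[15.0] <= exits[40.0] + 1e-9)
        assert np.all(exits[40.0] <= exits[150.0] + 1e-9)

    def test_hyperoxic_chamber_loads_blood(self, tiny_geom, params,
                                           tiny_control):
        res = run_steady_state(tiny_geom, params, make_chamber("full", 150.0),
                               initial=tiny_control.state)
        # blood takes up O2 over the hyperoxic outlet: exit above entrance
        assert np.all(res.S[:, -1] > params.S_in)
        assert np.all(res.state.j[:, -1] < 0)

    def test_myoglobin_facilitation_raises_minimum_po2(self, params,
                                                       control_condition):
        # consumption raised so the fixture develops a real hypoxic corner
        p1 = params.replace(M0=1e-3)
        g = make_tiny_network(4.0, p1)
        with_mb = run_steady_state(g, p1, control_condition)
        without = run_steady_state(g, p1.replace(c_Mb=0.0), control_condition,
                                   initial=with_mb.state)
        # myoglobin transport only ever adds down-gradient flux
        assert with_mb.P.min() >= without.P.min() - 1e-3
        assert with_mb.P.min() - without.P.min() > 0.005

    def test_blood_solubility_is_minor_correction(self, tiny_geom, params,
                                                  tiny_control):
        # erythrocyte/plasma solubilities enter only the small alpha_b terms
        # of the vessel balance: +-20% moves exit SO2 by well under 2%
        for f in (0.8, 1.2):
            p = params.replace(alpha_cell=f * params.alpha_cell,
                               alpha_pl=f * params.alpha_pl)
            res = run_steady_state(tiny_geom, p, tiny_control.chamber,
                                   initial=tiny_control.state)
            rel = np.abs(res.S[:, -1] - tiny_control.S[:, -1]) \
                / tiny_control.S[:, -1]
            assert rel.max() < 0.02

    def test_grid_refinement_consistency(self, params, control_condition):
        exits = {}
        for h in (4.0, 2.0):
            g = make_tiny_network(h, params)
            exits[h] = run_steady_state(g, params, control_condition).S[:, -1]
        rel = np.abs(exits[4.0] - exits[2.0]) / exits[2.0]
        assert rel.max() < 0.01

    def test_pseudo_time_reaches_same_fixed_point(self, tiny_geom, params,
                                                  tiny_control):
        num = NumericsConfig(method="pseudo_time", max_time_s=600.0,
                             dt_safety=0.25)
        res = run_steady_state(tiny_geom, params, tiny_control.chamber,
                               numerics=num)
        assert np.max(np.abs(res.S - tiny_control.S)) < 2e-3
        assert np.max(np.abs(res.P - tiny_control.P)) < 0.5


class TestKroghLimit:
    def test_angle_averaged_radial_profile(self):
        spec = make_single_capillary_fixture()
        res = run_steady_state(spec.geometry, spec.params, spec.chamber)
        g = spec.geometry.grid
        plane = res.P[:, g.Ny // 2, :]
        h = g.h_um
        ixc, izc = g.Nx // 2, g.Nz // 2

        def ring_mean(r_um, n=256):
            th = (np.arange(n) + 0.5) * 2 * np.pi / n
            xi = ixc + (r_um / h) * np.cos(th)
            zi = izc + (r_um / h) * np.sin(th)
            return ndimage.map_coordinates(plane, np.vstack([xi, zi]),
                                           order=1).mean()

        rs = np.arange(10.0, 29.0, 2.0)
        sim = np.array([ring_mean(r) for r in rs])
        ora = spec.oracle(rs, rs[0], sim[0])
        drop = ora[0] - ora[-1]
        assert drop > 5.0  # the fixture probes a resolvable gradient
        assert np.abs(sim - ora).max() < 0.05 * drop

    def test_wall_index_makes_exchange_grid_stable(self, params):
        # effective kappa shrinks when the sampling radius exceeds the wall
        g4 = make_tiny_network(4.0, params)
        k4 = kappa_effective(g4, params)
        assert np.all(k4 < params.kappa)
        assert np.all(k4 > 0.2 * params.kappa)
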
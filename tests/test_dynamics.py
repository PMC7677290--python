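"""Method-of-lines dynamics: operator, integrators, charging times."""

import math

import numpy as np
import pytest

import sphereq as sq
from sphereq.dynamics import assemble_operator, half_max_time, step_charging
from sphereq.experiments import sphere_for_ratio
from sphereq.reference import infinite_cable_charging, infinite_cable_half_time


class TestAngularGrid:
    def test_spans_cap_to_pole_uniformly(self):
        g = sq.AngularGrid(0.1, 65)
        th = g.nodes
        assert th[0] == 0.1
        assert th[-1] == pytest.approx(math.pi, rel=1e-15)
        assert np.allclose(np.diff(th), g.h)
        assert np.all(np.diff(th) > 0)

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            sq.AngularGrid(0.0, 10)
        with pytest.raises(ValueError):
            sq.AngularGrid(0.1, 1)


class TestOperator:
    def test_diffusion_annihilates_constants(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        op = assemble_operator(sq.AngularGrid(0.1, 101), membrane, geom)
        assert np.max(np.abs(op.diffusion_row_sums())) < 1e-20

    def test_legendre_p1_eigenfunction(self, membrane):
        # cos(theta) is the degree-1 Legendre mode: D cos = -2 (lam/rho)^2 cos
        geom = sphere_for_ratio(membrane, 1.0)
        lam = sq.electrotonic_length_sphere(membrane, geom)
        k = (lam / geom.rho) ** 2
        grid = sq.AngularGrid(0.1, 801)
        op = assemble_operator(grid, membrane, geom)
        got = op.apply_diffusion(np.cos(grid.nodes))
        want = -2.0 * k * np.cos(grid.nodes)
        interior = slice(5, -5)  # boundary rows encode the sealed/cap fluxes
        err = np.max(np.abs(got[interior] - want[interior]))
        assert err < 5e-4 * np.max(np.abs(want))

    def test_second_order_truncation_error(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        lam = sq.electrotonic_length_sphere(membrane, geom)
        k = (lam / geom.rho) ** 2
        errs = []
        for n in (201, 401):
            grid = sq.AngularGrid(0.1, n)
            op = assemble_operator(grid, membrane, geom)
            got = op.apply_diffusion(np.cos(grid.nodes))
            want = -2.0 * k * np.cos(grid.nodes)
            errs.append(np.max(np.abs(got - want)[5:-5]))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.3)

    def test_too_coarse_grid_rejected(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        with pytest.raises(ValueError):
            assemble_operator(sq.AngularGrid(0.1, 8), membrane, geom)


class TestSimulate:
    def test_uniform_mode_decays_with_tau(self, membrane):
        # diffusion is blind to a uniform profile; every node decays as e^-t/tau
        geom = sphere_for_ratio(membrane, 0.05)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        stim = sq.StimulusProtocol(kind="off")
        sol = sq.simulate(membrane, geom, electrode, stim, sq.AngularGrid(0.1, 64),
                          t_end=2 * membrane.tau, V0=1e-3, n_samples=50)
        expected = 1e-3 * np.exp(-sol.times / membrane.tau)
        assert np.allclose(sol.V, expected[None, :], rtol=1e-9, atol=1e-12)

    def test_rest_stays_at_rest(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        sol = sq.simulate(membrane, geom, electrode, sq.StimulusProtocol(kind="off"),
                          sq.AngularGrid(0.1, 64), t_end=membrane.tau, n_samples=20)
        assert np.all(sol.V == 0.0)

    def test_pulse_response_decays_with_membrane_time_constant(self, membrane):
        # south-pole response to a brief north-pole pulse: late log-slope -1/tau
        tau = membrane.tau
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        stim = sq.StimulusProtocol(kind="pulse", amplitude=1e-10, t_on=0.0,
                                   t_off=0.01 * tau)
        sol = sq.simulate(membrane, geom, electrode, stim, sq.AngularGrid(0.1, 256),
                          t_end=8 * tau, n_samples=800)
        late = sol.times > 5.0 * tau  # slowest (uniform) mode dominates
        slope = np.polyfit(sol.times[late], np.log(sol.V_southpole[late]), 1)[0]
        assert slope == pytest.approx(-1.0 / tau, rel=0.01)

    def test_superposition_in_amplitude_and_initial_state(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 128)
        tau = membrane.tau
        step = sq.StimulusProtocol(kind="step", amplitude=1e-10)
        off = sq.StimulusProtocol(kind="off")
        a = sq.simulate(membrane, geom, electrode, step, grid, t_end=tau, n_samples=40)
        b = sq.simulate(membrane, geom, electrode, off, grid, t_end=tau, V0=2e-3,
                        n_samples=40)
        both = sq.simulate(membrane, geom, electrode, step, grid, t_end=tau, V0=2e-3,
                           n_samples=40)
        scale = np.max(np.abs(both.V))
        assert np.max(np.abs(a.V + b.V - both.V)) < 1e-8 * scale

    def test_long_step_reaches_the_steady_profile(self, membrane):
        # cross-module gate: dynamics must converge to the analytic steady state
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 401)
        stim = sq.StimulusProtocol(kind="step", amplitude=1e-10)
        sol = sq.simulate(membrane, geom, electrode, stim, grid,
                          t_end=15 * membrane.tau, n_samples=60)
        steady = sq.steady_profile(membrane, geom, electrode, 1e-10,
                                   sq.AngularGrid(0.1, 201))
        final = np.interp(steady.grid.nodes, grid.nodes, sol.V[:, -1])
        assert np.max(np.abs(final - steady.V)) < 1e-3 * np.max(np.abs(steady.V))

    def test_bdf_matches_spectral_propagator(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 128)
        tau = membrane.tau
        stim = sq.StimulusProtocol(kind="pulse", amplitude=1e-10, t_on=0.1 * tau,
                                   t_off=0.6 * tau)
        exact = sq.simulate(membrane, geom, electrode, stim, grid, t_end=2 * tau,
                            n_samples=80, method="spectral")
        bdf = sq.simulate(membrane, geom, electrode, stim, grid, t_end=2 * tau,
                          n_samples=80, method="bdf", rtol=1e-9, atol=1e-14)
        scale = np.max(np.abs(exact.V))
        assert np.max(np.abs(exact.V - bdf.V)) < 1e-5 * scale


class TestClampReadout:
    def test_requires_voltage_clamp_mode(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        sol = sq.simulate(membrane, geom, electrode, sq.StimulusProtocol(kind="off"),
                          sq.AngularGrid(0.1, 64), t_end=membrane.tau, n_samples=10)
        with pytest.raises(ValueError):
            sq.clamp_current_readout(sol, membrane, geom, electrode)

    def test_zero_input_zero_clamp_current(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1, mode="voltage_clamp")
        sol = sq.simulate(membrane, geom, electrode, sq.StimulusProtocol(kind="off"),
                          sq.AngularGrid(0.1, 64), t_end=membrane.tau, n_samples=10)
        assert np.allclose(sol.I_clamp, 0.0, atol=1e-25)

    def test_injection_through_clamped_cap_rejected(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1, mode="voltage_clamp")
        stim = sq.StimulusProtocol(kind="step", amplitude=1e-10, site="pipette_cap")
        with pytest.raises(ValueError):
            sq.simulate(membrane, geom, electrode, stim, sq.AngularGrid(0.1, 64),
                        t_end=membrane.tau)

    def test_plateau_current_budget_closes(self, membrane):
        # at the plateau: injected step = clamp current + membrane leak
        geom = sphere_for_ratio(membrane, 0.5)
        electrode = sq.ElectrodeConfig(theta_a=0.1, mode="voltage_clamp")
        res = sq.sphere_clamp_experiment(membrane, geom, electrode, N=400)
        assert res.diagnostics["budget_residual"] < 0.01


class TestHalfMaxTime:
    def test_rc_trace(self):
        # the plateau estimate (mean of the last 5% of samples) needs a long
        # horizon for its bias e^-t_end/tau to clear the 1e-4 comparison
        tau = 0.1
        t = np.linspace(0, 20 * tau, 8000)
        got = half_max_time(t, 1 - np.exp(-t / tau))
        assert got == pytest.approx(tau * math.log(2), rel=1e-4)

    def test_infinite_cable_trace(self):
        tau = 0.1
        t = np.linspace(0, 20 * tau, 8000)
        got = half_max_time(t, infinite_cable_charging(t, tau))
        assert got == pytest.approx(infinite_cable_half_time(tau), rel=1e-3)

    def test_unconverged_trace_rejected(self):
        tau = 1.0
        t = np.linspace(0, tau, 100)  # far from plateau
        with pytest.raises(ValueError, match="t_end"):
            half_max_time(t, 1 - np.exp(-t / tau))


class TestChargingTime:
    def test_adipocyte_charges_slightly_faster_than_a_compartment(self, adipocyte):
        membrane, geom, electrode, _ = adipocyte
        res = step_charging(membrane, geom, electrode,
                            grid=sq.AngularGrid(electrode.theta_a, 1000))
        # two-timescale expansion: ln 2 - ln(1 + f), f the spreading fraction
        f = (membrane.r_i / (2 * math.pi * geom.d)
             * math.log(2 / electrode.theta_a)) * (4 * math.pi * geom.rho**2 / membrane.r_m)
        assert res.t_half_over_tau < math.log(2)
        assert res.t_half_over_tau == pytest.approx(math.log(2) - math.log1p(f), abs=1e-3)

    def test_grid_refinement_stability(self, adipocyte):
        membrane, geom, electrode, _ = adipocyte
        vals = [
            step_charging(membrane, geom, electrode,
                          grid=sq.AngularGrid(electrode.theta_a, n)).t_half_over_tau
            for n in (500, 1000)
        ]
        assert vals[0] == pytest.approx(vals[1], rel=1e-3)

    def test_sphere_at_lambda_beats_compartment_and_cable(self, membrane):
        # rho = lambda, theta_a = 0.1: charging faster than both references
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        res = step_charging(membrane, geom, electrode, grid=sq.AngularGrid(0.1, 800))
        assert res.t_half_over_tau < infinite_cable_half_time(1.0)
        assert res.t_half_over_tau < math.log(2)

    def test_discharge_mirrors_charge(self, membrane):
        # remove a sustained current after equilibrium: the decay half-time
        # equals the charging half-time (linearity + step time reversal)
        tau = membrane.tau
        geom = sphere_for_ratio(membrane, 0.3)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 400)
        charge = step_charging(membrane, geom, electrode, grid=grid)
        stim = sq.StimulusProtocol(kind="pulse", amplitude=1e-10, t_on=0.0,
                                   t_off=12 * tau)
        sol = sq.simulate(membrane, geom, electrode, stim, grid, t_end=24 * tau,
                          n_samples=6000)
        decay_sel = sol.times >= 12 * tau
        t_dec = sol.times[decay_sel] - 12 * tau
        v_dec = sol.V_pipette[decay_sel]
        v0 = v_dec[0]
        k = int(np.argmax(v_dec <= 0.5 * v0))
        t_half_dec = np.interp(0.5 * v0, v_dec[[k, k - 1]], t_dec[[k, k - 1]])
        assert t_half_dec == pytest.approx(charge.t_half, rel=5e-3)
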
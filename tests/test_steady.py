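"""Steady-state solution: oracles, conservation, asymptotics, input resistance."""

import math

import numpy as np
import pytest

import sphereq as sq
from sphereq.experiments import sphere_for_ratio
from sphereq.steady import _conservation_error

from conftest import RATIOS, fv_on_grid


class TestConicalQSum:
    def test_imaginary_parts_cancel_in_conical_regime(self):
        # conjugate-degree pair: Im(Q_{nu+}) = -Im(Q_{nu-}); the sum is real
        rng = np.random.default_rng(7)
        for ratio in rng.uniform(0.5, 3.0, size=6):
            nu = sq.nu_roots(ratio, 1.0)
            for x in (-0.9, 0.0, 0.9):
                val = sq.conical_Q_sum(nu, x)  # raises if the residue survives
                assert np.isfinite(val)

    def test_near_degree_pole_regime_matches_shooting(self, membrane):
        # compact sphere: nu+ ~ -3e-4 sits next to the Q degree pole at -1
        geom = sq.SphereGeometry(rho=40e-6, d=0.5e-6)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 101)
        leg = sq.steady_profile(membrane, geom, electrode, 1e-10, grid)
        sho = sq.shooting_oracle(membrane, geom, electrode, 1e-10, grid)
        assert np.max(np.abs(leg.V - sho.V)) < 1e-6 * np.max(np.abs(leg.V))

    def test_conical_value_against_ode_integration(self, membrane):
        # rho = lambda, theta = 1.0: ratio of the profile at two angles is a
        # pure shape quantity, independent of normalization
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 2001)
        sho = sq.shooting_oracle(membrane, geom, electrode, 1e-10, grid)
        nu = sq.nu_roots(1.0, 1.0)
        q1 = sq.conical_Q_sum(nu, math.cos(1.0))
        q2 = sq.conical_Q_sum(nu, math.cos(2.0))
        v1 = np.interp(1.0, grid.nodes, sho.V)
        v2 = np.interp(2.0, grid.nodes, sho.V)
        assert q1 / q2 == pytest.approx(v1 / v2, rel=1e-5)


class TestOracleEquivalence:
    @pytest.mark.parametrize("ratio", RATIOS)
    def test_three_routes_agree(self, oracle_profiles, ratio):
        leg, sho, fv = oracle_profiles[ratio]
        scale = np.max(np.abs(leg.V))
        assert np.max(np.abs(leg.V - sho.V)) < 1e-4 * scale
        assert np.max(np.abs(leg.V - fv_on_grid(fv, leg.grid))) < 1e-4 * scale

    @pytest.mark.parametrize("ratio", RATIOS)
    def test_conservation_identity(self, oracle_profiles, ratio):
        for prof in oracle_profiles[ratio]:
            assert _conservation_error(prof) < 1e-4

    @pytest.mark.parametrize("ratio", RATIOS)
    def test_profile_strictly_decreasing(self, oracle_profiles, ratio):
        leg, _, _ = oracle_profiles[ratio]
        assert np.all(np.diff(leg.V) < 0)

    def test_sealed_south_pole(self, oracle_profiles):
        leg, _, _ = oracle_profiles[1.0]
        h = leg.grid.h
        end_slope = (leg.V[-1] - leg.V[-2]) / h
        max_slope = np.max(np.abs(np.diff(leg.V))) / h
        assert abs(end_slope) < 2e-2 * max_slope
        assert np.all(np.isfinite(leg.V))


class TestNormalization:
    def test_b_linear_in_current(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        b1 = sq.normalization_b(membrane, geom, electrode, 1e-10)
        b2 = sq.normalization_b(membrane, geom, electrode, 2e-10)
        assert b2 == pytest.approx(2 * b1, rel=1e-12)

    def test_depolarizing_current_raises_cap_voltage(self, oracle_profiles):
        for ratio in RATIOS:
            leg, _, _ = oracle_profiles[ratio]
            assert leg.V_pipette > 0

    def test_profile_scales_linearly_with_current(self, membrane):
        geom = sphere_for_ratio(membrane, 0.5)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 101)
        p1 = sq.shooting_oracle(membrane, geom, electrode, 1e-10, grid)
        p2 = sq.shooting_oracle(membrane, geom, electrode, 3e-10, grid)
        assert np.allclose(p2.V, 3 * p1.V, rtol=1e-10)


class TestInputResistance:
    def test_adipocyte_value_against_envelope_oracle(self, adipocyte):
        # compact-sphere envelope: whole-membrane leak plus the spreading
        # resistance of the narrow cap, r_m/4 pi rho^2 + (r_i/2 pi d) ln(2/theta_a)
        membrane, geom, electrode, _ = adipocyte
        prof = sq.steady_profile(membrane, geom, electrode, 1e-10,
                                 sq.AngularGrid(electrode.theta_a, 201))
        r_in = sq.input_resistance(prof)
        envelope = (
            membrane.r_m / (4 * math.pi * geom.rho**2)
            + membrane.r_i / (2 * math.pi * geom.d) * math.log(2 / electrode.theta_a)
        )
        assert r_in == pytest.approx(envelope, rel=0.01)
        assert r_in / 1e6 == pytest.approx(498.7, rel=1e-3)

    def test_compact_limit_reaches_single_compartment(self, membrane):
        # rho/lambda -> 0 with a small cap: spreading term and excluded cap
        # area both negligible, so R_in -> r_m / (4 pi rho^2)
        geom = sphere_for_ratio(membrane, 1e-3, d=0.02e-6)
        electrode = sq.ElectrodeConfig(theta_a=0.05)
        prof = sq.shooting_oracle(membrane, geom, electrode, 1e-10,
                                  sq.AngularGrid(0.05, 201))
        r_comp = membrane.r_m / (4 * math.pi * geom.rho**2)
        assert sq.input_resistance(prof) == pytest.approx(r_comp, rel=5e-3)

    def test_zero_current_rejected(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        prof = sq.shooting_oracle(membrane, geom, electrode, 1e-10,
                                  sq.AngularGrid(0.1, 101))
        prof.I_ext = 0.0
        with pytest.raises(ValueError):
            sq.input_resistance(prof)


class TestPipetteDivergence:
    def test_log_divergence_increment(self, membrane):
        # V(theta_a) - V(theta_a/2) -> (I r_i / 2 pi d) ln 2 as theta_a -> 0
        geom = sphere_for_ratio(membrane, 1.0)
        I = 1e-10
        vals = {}
        for th_a in (0.01, 0.005):
            prof = sq.shooting_oracle(membrane, geom, sq.ElectrodeConfig(theta_a=th_a),
                                      I, sq.AngularGrid(th_a, 2001))
            vals[th_a] = prof.V_pipette
        expected = I * membrane.r_i / (2 * math.pi * geom.d) * math.log(2)
        assert vals[0.005] - vals[0.01] == pytest.approx(expected, rel=0.05)

    def test_asymptote_scales_inversely_with_shell(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        thick = sq.SphereGeometry(rho=geom.rho, d=2 * geom.d)
        a1 = sq.pipette_log_asymptote(membrane, geom, 0.01, 1e-10)
        a2 = sq.pipette_log_asymptote(membrane, thick, 0.01, 1e-10)
        assert a2 == pytest.approx(a1 / 2, rel=1e-12)


class TestLeakIntegral:
    def test_zero_profile_gives_zero(self, membrane):
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 101)
        prof = sq.SteadyProfile(grid=grid, V=np.zeros(101), params=membrane,
                                geom=geom, electrode=electrode, I_ext=0.0)
        assert sq.leak_integral(prof) == 0.0

    def test_second_order_quadrature_refinement(self, membrane):
        # halving the spacing shrinks the conservation error ~4x
        geom = sphere_for_ratio(membrane, 1.0)
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        errs = []
        for n in (101, 201):
            prof = sq.shooting_oracle(membrane, geom, electrode, 1e-10,
                                      sq.AngularGrid(0.1, n))
            errs.append(_conservation_error(prof))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.5)


class TestRegimeContinuity:
    def test_profiles_continuous_across_root_transition(self, membrane):
        # real <-> conical switch at rho/lambda = 1/2 is analytic in the
        # physics: the profile varies smoothly through the double root, so
        # the second difference across it vanishes to O(step^2) while the
        # one-sided steps carry the ordinary smooth parametric drift
        electrode = sq.ElectrodeConfig(theta_a=0.1)
        grid = sq.AngularGrid(0.1, 101)
        lo = sq.steady_profile(membrane, sphere_for_ratio(membrane, 0.499),
                               electrode, 1e-10, grid)
        mid = sq.steady_profile(membrane, sphere_for_ratio(membrane, 0.5),
                                electrode, 1e-10, grid)
        hi = sq.steady_profile(membrane, sphere_for_ratio(membrane, 0.501),
                               electrode, 1e-10, grid)
        scale = np.max(np.abs(mid.V))
        assert np.max(np.abs(lo.V + hi.V - 2 * mid.V)) < 1e-4 * scale
        assert np.max(np.abs(hi.V - lo.V)) < 2e-2 * scale


class TestCompactSphere:
    def test_adipocyte_is_electrotonically_compact(self, adipocyte):
        membrane, geom, electrode, _ = adipocyte
        prof = sq.steady_profile(membrane, geom, electrode, 1e-10,
                                 sq.AngularGrid(electrode.theta_a, 201))
        interior = prof.V[1:]  # exclude the cap node with its spreading bump
        assert (interior.max() - interior.min()) < 0.01 * interior.mean()

    def test_large_sphere_voltage_barely_reaches_south_pole(self, oracle_profiles):
        leg, _, _ = oracle_profiles[2**0.5]
        assert leg.V[-1] < 0.05 * leg.V_pipette
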
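"""Analytic steady state of the sphere equation and its oracles.

With the time derivative dropped, the sphere equation becomes Legendre's
equation in x = cos(theta) with degree nu satisfying nu(nu+1) = -rho^2/lambda^2,
i.e. nu+- = -1/2 +- (1/2) sqrt(1 - 4 rho^2/lambda^2).  The solution that is
regular (sealed) at the south pole is the pair sum

    V(theta) = b [ Q_{nu+}(cos theta) + Q_{nu-}(cos theta) ],

which stays finite at theta = pi in the real-root regime (rho/lambda <= 1/2,
the individual Q's diverge there but their sum does not) and is real in the
conical regime (rho/lambda > 1/2, where the imaginary parts of the
conjugate-degree pair cancel).  The normalization b follows from the
electrode flux condition V'(theta_a) = -I r_i/(2 pi d sin theta_a):

    b = I r_i / (2 pi d sin^2(theta_a) [Q'_{nu+}(x_a) + Q'_{nu-}(x_a)]),

with Q' = dQ/dx and x_a = cos(theta_a); the sin^2 collects the chain-rule
factor dx/dtheta = -sin(theta).

Q at complex degree is evaluated with mpmath at elevated precision; the
working precision grows automatically near the degree poles nu in {0, -1}
(the electrotonically compact regime, where the pair sum is a delicate
limit).  An independent shooting oracle integrates the same ODE from the
regular point theta = pi with scipy and rescales to the flux condition;
the two paths agree to ~1e-6 and both satisfy the current-conservation
identity used as the accuracy self-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import mpmath as mp
import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import AngularGrid, _current_clamp_system, assemble_operator
from .params import (
    ElectrodeConfig,
    MembraneParams,
    NuRoots,
    SphereGeometry,
    electrotonic_length_sphere,
    nu_roots,
)

__all__ = [
    "SteadyProfile",
    "conical_Q_sum",
    "conical_Q_sum_deriv",
    "normalization_b",
    "steady_profile",
    "shooting_oracle",
    "discrete_steady_profile",
    "input_resistance",
    "pipette_log_asymptote",
    "leak_integral",
]

_IM_TOL = 1e-10


def _working_dps(nu: NuRoots) -> int:
    # near the degree poles the pair sum loses ~log10(1/|nu+|) digits
    gap = min(abs(nu.nu_plus), abs(nu.nu_plus + 1))
    extra = 0 if gap == 0 else max(0.0, -mp.log10(gap))
    return int(30 + min(extra, 60))


def conical_Q_sum(nu: NuRoots, x: float, dps: int | None = None) -> float:
    """Q_{nu+}(x) + Q_{nu-}(x) for x in (-1, 1), guaranteed real.

    Valid in both degree regimes; raises if the imaginary residue exceeds
    1e-10 relative (it cancels identically in exact arithmetic).
    """
    if not -1.0 < x < 1.0:
        raise ValueError("x must lie in (-1, 1)")
    with mp.workdps(dps or _working_dps(nu)):
        total = mp.legenq(mp.mpc(nu.nu_plus), 0, mp.mpc(x), type=2) + mp.legenq(
            mp.mpc(nu.nu_minus), 0, mp.mpc(x), type=2
        )
        re, im = float(mp.re(total)), float(mp.im(total))
    if re != 0.0 and abs(im) > _IM_TOL * abs(re):
        raise ArithmeticError(
            f"imaginary residue {im:g} did not cancel against real part {re:g}"
        )
    return re


def conical_Q_sum_deriv(nu: NuRoots, x: float, dps: int | None = None) -> float:
    """d/dx of the pair sum, by arbitrary-precision differentiation."""
    if not -1.0 < x < 1.0:
        raise ValueError("x must lie in (-1, 1)")
    with mp.workdps(dps or _working_dps(nu)):
        d = mp.diff(
            lambda z: mp.legenq(mp.mpc(nu.nu_plus), 0, z, type=2)
            + mp.legenq(mp.mpc(nu.nu_minus), 0, z, type=2),
            mp.mpc(x),
        )
        re, im = float(mp.re(d)), float(mp.im(d))
    if re != 0.0 and abs(im) > _IM_TOL * abs(re):
        raise ArithmeticError("imaginary residue of Q' did not cancel")
    return re


@dataclass
class SteadyProfile:
    """Steady-state voltage V(theta) on an angular grid.

    The cap region theta < theta_a is equipotential at V[0].  ``b`` is the
    Legendre normalization (NaN for purely numerical constructions).
    """

    grid: AngularGrid
    V: np.ndarray
    params: MembraneParams
    geom: SphereGeometry
    electrode: ElectrodeConfig
    I_ext: float
    b: float = math.nan
    diagnostics: dict = field(default_factory=dict)

    @property
    def V_pipette(self) -> float:
        return float(self.V[0])


def normalization_b(
    params: MembraneParams,
    geom: SphereGeometry,
    electrode: ElectrodeConfig,
    I_ext: float,
) -> float:
    """Normalization constant b of the steady profile [V].

    Linear in the injected current; for theta_a -> 0 it stays finite while
    the cap voltage diverges like -log(theta_a) (the pipette divergence).
    """
    lam = electrotonic_length_sphere(params, geom)
    nu = nu_roots(geom.rho, lam)
    th_a = electrode.theta_a
    dq = conical_Q_sum_deriv(nu, math.cos(th_a))
    return I_ext * params.r_i / (2.0 * math.pi * geom.d * math.sin(th_a) ** 2 * dq)


def steady_profile(
    params: MembraneParams,
    geom: SphereGeometry,
    electrode: ElectrodeConfig,
    I_ext: float,
    grid: AngularGrid | None = None,
) -> SteadyProfile:
    """Steady state from the closed-form Legendre pair (the primary path)."""
    if grid is None:
        grid = AngularGrid(electrode.theta_a, 501)
    lam = electrotonic_length_sphere(params, geom)
    nu = nu_roots(geom.rho, lam)
    b = normalization_b(params, geom, electrode, I_ext)
    th = grid.nodes
    V = np.empty(grid.N)
    dps = _working_dps(nu)
    for j, t in enumerate(th):
        if t >= math.pi:  # regularized south-pole limit of the pair sum
            V[j] = _qsum_at_pole(nu, dps)
        else:
            V[j] = conical_Q_sum(nu, math.cos(t), dps=dps)
    V *= b
    V += params.E
    prof = SteadyProfile(
        grid=grid, V=V, params=params, geom=geom, electrode=electrode,
        I_ext=I_ext, b=b, diagnostics={"method": "legendre", "nu_plus": nu.nu_plus},
    )
    prof.diagnostics["conservation_error"] = _conservation_error(prof)
    return prof


def _qsum_at_pole(nu: NuRoots, dps: int) -> float:
    # Q_{nu+}+Q_{nu-} is finite at x=-1; evaluate just off the pole and
    # extrapolate (the sum approaches its limit linearly in 1+x).
    eps = 1e-7
    f1 = conical_Q_sum(nu, -1.0 + eps, dps=dps + 10)
    f2 = conical_Q_sum(nu, -1.0 + 2 * eps, dps=dps + 10)
    return 2.0 * f1 - f2


def shooting_oracle(
    params: MembraneParams,
    geom: SphereGeometry,
    electrode: ElectrodeConfig,
    I_ext: float,
    grid: AngularGrid | None = None,
    rtol: float = 1e-11,
) -> SteadyProfile:
    """Steady state by shooting from the regular point theta = pi.

    The regular-at-pi solution of the steady ODE is unique up to scale, so
    integrating from the pole with (V, V') = (1, 0) and rescaling to the
    electrode flux condition reproduces the Legendre profile without any
    special functions.  Reliable for rho/lambda up to ~5 (beyond that the
    solution grows so steeply that the closed form or the discrete solver
    should be preferred).
    """
    if grid is None:
        grid = AngularGrid(electrode.theta_a, 501)
    lam = electrotonic_length_sphere(params, geom)
    k2 = (geom.rho / lam) ** 2
    th_a = electrode.theta_a

    # integrate in u = pi - theta from the pole; series start lifts the 0/0
    def rhs(u, y):
        V, W = y
        return [W, k2 * V - W / math.tan(u)]

    u0 = 1e-8
    y0 = [1.0 + k2 * u0 * u0 / 4.0, k2 * u0 / 2.0]
    u_eval = (math.pi - grid.nodes)[::-1]
    u_eval[0] = max(u_eval[0], u0)
    sol = solve_ivp(
        rhs, (u0, math.pi - th_a), y0, t_eval=u_eval, rtol=rtol, atol=1e-14,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"shooting integration failed: {sol.message}")
    V_unscaled = sol.y[0][::-1].copy()
    # dV/dtheta = -dV/du; flux condition at theta_a
    dV_dth_unscaled = -sol.y[1, -1]
    target = -I_ext * params.r_i / (2.0 * math.pi * geom.d * math.sin(th_a))
    scale = target / dV_dth_unscaled if dV_dth_unscaled != 0 else math.nan
    V = scale * V_unscaled + params.E
    prof = SteadyProfile(
        grid=grid, V=V, params=params, geom=geom, electrode=electrode,
        I_ext=I_ext, diagnostics={"method": "shooting", "scale": scale},
    )
    prof.diagnostics["conservation_error"] = _conservation_error(prof)
    return prof


def discrete_steady_profile(
    params: MembraneParams,
    geom: SphereGeometry,
    electrode: ElectrodeConfig,
    I_ext: float,
    grid: AngularGrid | None = None,
) -> SteadyProfile:
    """Steady state of the finite-volume circuit (the dynamic solver's limit)."""
    if grid is None:
        grid = AngularGrid(electrode.theta_a, 2001)
    op = assemble_operator(grid, params, geom)
    sys_ = _current_clamp_system(op)
    b = np.zeros(grid.N)
    b[0] = I_ext
    b += op.leak * params.E
    V = sys_.steady(b)
    prof = SteadyProfile(
        grid=grid, V=V, params=params, geom=geom, electrode=electrode,
        I_ext=I_ext, diagnostics={"method": "finite_volume"},
    )
    prof.diagnostics["conservation_error"] = _conservation_error(prof)
    return prof


def input_resistance(profile: SteadyProfile) -> float:
    """R_in = V(theta_a) / I_ext [Ohm] (voltages measured from rest)."""
    if profile.I_ext == 0:
        raise ValueError("input resistance is undefined for zero injected current")
    return (profile.V_pipette - profile.params.E) / profile.I_ext


def pipette_log_asymptote(
    params: MembraneParams, geom: SphereGeometry, theta_a: float, I_ext: float
) -> float:
    """Divergent part of the cap voltage for a narrow pipette [V].

    V(theta_a) ~ -(I r_i / 2 pi d) log(theta_a); the exact profile differs
    by an additive O(1) offset that is independent of theta_a.
    """
    return -I_ext * params.r_i / (2.0 * math.pi * geom.d) * math.log(theta_a)


def leak_integral(profile: SteadyProfile) -> float:
    """Total membrane leak (2 pi rho^2 / r_m) int V sin(theta) dtheta [A].

    Composite trapezoid on the profile's own grid (matching the solver's
    second order); equals I_ext for an accurate steady profile, which is
    the standard conservation self-check.
    """
    th = profile.grid.nodes
    V = profile.V - profile.params.E
    integrand = V * np.sin(th)
    return (
        2.0 * math.pi * profile.geom.rho**2 / profile.params.r_m
        * float(np.trapezoid(integrand, th))
    )


def _conservation_error(profile: SteadyProfile) -> float:
    if profile.I_ext == 0:
        return 0.0
    return abs(leak_integral(profile) - profile.I_ext) / abs(profile.I_ext)
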
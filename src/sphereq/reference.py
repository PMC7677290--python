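"""Single-compartment and cable reference models.

These are the standard comparison points for the sphere: an isopotential
RC compartment charges as 1 - exp(-t/tau) (half-maximum at tau*ln2), the
injection site of an infinite cable as erf(sqrt(t/tau)) (half-maximum at
(erfinv 1/2)^2 tau ~ 0.2275 tau), and a finite sealed-end cable
interpolates between the two as L/lambda shrinks.  The finite cable is
solved with the same conservative finite-volume/method-of-lines machinery
as the sphere so that cross-geometry comparisons are not confounded by
scheme differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, erfinv

from .dynamics import _TridiagLTI
from .params import (
    CableGeometry,
    MembraneParams,
    StimulusProtocol,
    electrotonic_length_cable,
)

__all__ = [
    "CompartmentModel",
    "CableSolution",
    "compartment_step_response",
    "sphere_compartment_resistance",
    "infinite_cable_charging",
    "infinite_cable_half_time",
    "cable_steady_end_injection",
    "finite_cable_solver",
    "cable_circuit",
]


@dataclass(frozen=True)
class CompartmentModel:
    """Isopotential RC compartment: total resistance R [Ohm], time constant tau [s]."""

    R: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.tau > 0):
            raise ValueError("R and tau must be positive")

    def step_response(self, I: float, t) -> np.ndarray:
        return compartment_step_response(self.R, self.tau, I, t)


def compartment_step_response(R: float, tau: float, I: float, t) -> np.ndarray:
    """V(t) = I R (1 - exp(-t/tau)) for a step current from t=0."""
    t = np.asarray(t, dtype=float)
    return I * R * (1.0 - np.exp(-t / tau))


def sphere_compartment_resistance(params: MembraneParams, geom) -> float:
    """Single-compartment resistance of the whole sphere membrane r_m/(4 pi rho^2)."""
    return params.r_m / (4.0 * math.pi * geom.rho**2)


def infinite_cable_charging(t, tau: float) -> np.ndarray:
    """Normalized charging at the injection site of an infinite cable: erf(sqrt(t/tau))."""
    t = np.asarray(t, dtype=float)
    return erf(np.sqrt(np.clip(t, 0.0, None) / tau))


def infinite_cable_half_time(tau: float) -> float:
    """Closed-form half-maximum time (erfinv 1/2)^2 tau ~ 0.2275 tau."""
    return float(erfinv(0.5) ** 2) * tau


def cable_steady_end_injection(
    params: MembraneParams, geom: CableGeometry, I: float, x: np.ndarray
) -> np.ndarray:
    """Steady profile for current I injected at x=0 of a sealed finite cable.

    V(x) = I r_a lambda cosh((L-x)/lambda)/sinh(L/lambda), with r_a the
    axial resistance per unit length 4 r_i/(pi d_cable^2).
    """
    lam = electrotonic_length_cable(params, geom)
    r_a = 4.0 * params.r_i / (math.pi * geom.d_cable**2)
    x = np.asarray(x, dtype=float)
    return I * r_a * lam * np.cosh((geom.L - x) / lam) / math.sinh(geom.L / lam)


def cable_circuit(
    params: MembraneParams, geom: CableGeometry, N: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Finite-volume circuit of the sealed cable: (x, C, leak, g_axial)."""
    if geom.is_infinite:
        raise ValueError("finite-volume cable needs a finite length")
    x = np.linspace(0.0, geom.L, N)
    h = x[1] - x[0]
    circumference = math.pi * geom.d_cable
    areas = np.full(N, circumference * h)
    areas[0] = areas[-1] = circumference * h / 2.0
    g = np.full(N - 1, math.pi * geom.d_cable**2 / (4.0 * params.r_i * h))
    return x, params.c_m * areas, areas / params.r_m, g


@dataclass
class CableSolution:
    """Method-of-lines solution of the sealed-end cable equation."""

    x: np.ndarray
    times: np.ndarray
    V: np.ndarray                       # (N, n_times)
    lam_cable: float
    tau: float
    I_clamp: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def V_x0(self) -> np.ndarray:
        return self.V[0, :]

    @property
    def V_xL(self) -> np.ndarray:
        return self.V[-1, :]


def finite_cable_solver(
    params: MembraneParams,
    geom: CableGeometry,
    stimulus: StimulusProtocol,
    injection_end: str = "x0",
    clamp_end: str | None = None,
    clamp_potential: float = 0.0,
    footprint: float = 0.0,
    t_end: float | None = None,
    N: int = 800,
    n_samples: int = 400,
) -> CableSolution:
    """Simulate the sealed finite cable with an end electrode.

    ``injection_end`` selects where the stimulus current enters ("x0" or
    "xL"); ``footprint`` > 0 spreads it uniformly over that length of cable
    instead of the end node (the cable analogue of a pipette's finite size,
    used to show that, unlike the sphere, the cable end voltage barely
    cares).  ``clamp_end`` turns that end into a voltage-clamp Dirichlet
    node and attaches the clamp-current trace read from the end flux.
    Both ends are otherwise sealed (zero axial flux), which the half-cell
    control volumes encode naturally.  Integration is by the exact spectral
    propagator between stimulus switch times.
    """
    if injection_end not in ("x0", "xL"):
        raise ValueError("injection_end must be 'x0' or 'xL'")
    if clamp_end is not None and clamp_end == injection_end:
        raise ValueError("cannot clamp and inject at the same end")
    tau = params.tau
    if t_end is None:
        t_end = 8.0 * tau
    x, C, leak, g = cable_circuit(params, geom, N)
    h = x[1] - x[0]

    # unit spatial distribution of the injected current
    dist = np.zeros(N)
    if footprint > 0.0:
        mask = (x <= footprint) if injection_end == "x0" else (x >= geom.L - footprint)
        if not mask.any():
            raise ValueError("footprint smaller than the grid spacing")
        w = np.where(mask, np.where((x == 0) | (x == geom.L), 0.5, 1.0), 0.0)
        dist = w / w.sum()
    else:
        dist[0 if injection_end == "x0" else -1] = 1.0

    clamp_idx = None
    if clamp_end is not None:
        clamp_idx = 0 if clamp_end == "x0" else N - 1

    if clamp_idx is None:
        diag = leak.copy()
        diag[:-1] += g
        diag[1:] += g
        sys_ = _TridiagLTI(C, diag, -g)
        keep = np.arange(N)
        base_b = np.zeros(N)
    elif clamp_idx == 0:
        diag = leak[1:].copy()
        diag[:-1] += g[1:]
        diag[1:] += g[1:]
        diag[0] += g[0]
        sys_ = _TridiagLTI(C[1:], diag, -g[1:])
        keep = np.arange(1, N)
        base_b = np.zeros(N - 1)
        base_b[0] += g[0] * clamp_potential
    else:
        diag = leak[:-1].copy()
        diag[:-1] += g[:-1]
        diag[1:] += g[:-1]
        diag[-1] += g[-1]
        sys_ = _TridiagLTI(C[:-1], diag, -g[:-1])
        keep = np.arange(0, N - 1)
        base_b = np.zeros(N - 1)
        base_b[-1] += g[-1] * clamp_potential

    unit_b = dist[keep]
    times = np.linspace(0.0, t_end, n_samples)
    for t in stimulus.switch_times():
        if 0.0 < t < t_end:
            times = np.union1d(times, [t])
    cuts = sorted({0.0, t_end, *[t for t in stimulus.switch_times() if 0 < t < t_end]})
    V = np.zeros((N, times.size))
    Vfree = np.zeros(keep.size)
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        amp = stimulus.current(0.5 * (t0 + t1))
        b = base_b + amp * unit_b
        sel = (times >= t0) & (times <= t1)
        V[keep[:, None], np.where(sel)[0][None, :]] = sys_.evolve(Vfree, b, times[sel] - t0)
        Vfree = sys_.evolve(Vfree, b, np.array([t1 - t0]))[:, 0]

    sol = CableSolution(
        x=x, times=times, V=V, lam_cable=electrotonic_length_cable(params, geom),
        tau=tau, diagnostics={"N": N, "method": "spectral"},
    )
    if clamp_idx is not None:
        V[clamp_idx, :] = clamp_potential
        axial = math.pi * geom.d_cable**2 / (4.0 * params.r_i)
        if clamp_idx == 0:
            dVdx = (-3.0 * V[0, :] + 4.0 * V[1, :] - V[2, :]) / (2.0 * h)
            sol.I_clamp = axial * dVdx       # current collected by the clamp
        else:
            dVdx = (3.0 * V[-1, :] - 4.0 * V[-2, :] + V[-3, :]) / (2.0 * h)
            sol.I_clamp = -axial * dVdx
    return sol
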
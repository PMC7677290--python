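"""Parameter containers and derived electrotonic quantities.

The passive electrical state of a thin-shell spherical cell (e.g. a white
adipocyte, whose lipid droplet confines current flow to a ~0.5 µm
cytoplasmic shell) is controlled by two derived parameters:

* the membrane time constant ``tau = r_m * c_m``, and
* the ratio of the cell radius ``rho`` to the electrotonic length
  ``lambda = sqrt(r_m * d / r_i)`` of the shell.

For comparison with neurites, the cylinder (cable) electrotonic length is
``lambda_cable = sqrt(d_cable * r_m / (4 r_i))``; apart from the geometric
factor 2 and the meaning of ``d`` it matches the sphere expression.

All fields are SI; use :mod:`sphereq.units` / :mod:`sphereq.config` to get
here from conventional electrophysiology units.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "MembraneParams",
    "SphereGeometry",
    "CableGeometry",
    "ElectrodeConfig",
    "StimulusProtocol",
    "NuRoots",
    "membrane_time_constant",
    "electrotonic_length_sphere",
    "electrotonic_length_cable",
    "nu_roots",
    "pipette_half_angle",
]


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane constants.

    c_m : specific capacitance [F/m^2]
    r_m : specific membrane resistance [Ohm m^2]
    r_i : intracellular resistivity [Ohm m]
    E   : leak reversal potential [V]; offsets all voltages and nothing
          else, so the default 0 means voltages are deviations from rest.
    """

    c_m: float
    r_m: float
    r_i: float
    E: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_m", "r_m", "r_i"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def tau(self) -> float:
        """Membrane time constant r_m * c_m [s]."""
        return self.r_m * self.c_m


@dataclass(frozen=True)
class SphereGeometry:
    """Sphere of radius ``rho`` with a conducting shell of thickness ``d`` [m].

    The thin-shell description assumes ``d << rho``; a shell thicker than
    10% of the radius triggers a warning (not an error).
    """

    rho: float
    d: float

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")
        if self.d / self.rho > 0.1:
            warnings.warn(
                f"shell thickness d={self.d:g} m is more than 10% of the radius "
                f"rho={self.rho:g} m; the thin-shell assumption d << rho is strained",
                stacklevel=3,
            )

    def lam(self, membrane: MembraneParams) -> float:
        """Electrotonic length sqrt(r_m d / r_i) [m]."""
        return electrotonic_length_sphere(membrane, self)


@dataclass(frozen=True)
class CableGeometry:
    """Cylinder of diameter ``d_cable`` and length ``L`` [m] (L=inf allowed)."""

    d_cable: float
    L: float

    def __post_init__(self) -> None:
        if not self.d_cable > 0:
            raise ValueError(f"d_cable must be positive, got {self.d_cable}")
        if not self.L > 0:
            raise ValueError(f"L must be positive, got {self.L}")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.L)

    def lam(self, membrane: MembraneParams) -> float:
        """Cable electrotonic length sqrt(d_cable r_m / 4 r_i) [m]."""
        return electrotonic_length_cable(membrane, self)


CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


@dataclass(frozen=True)
class ElectrodeConfig:
    """Pipette electrode covering the polar cap ``theta <= theta_a``.

    The cap is equipotential with no membrane leak or capacitance under it;
    in current clamp all injected current exits the cap rim as a lateral
    flux at latitude ``theta_a``, in voltage clamp the cap is held at
    ``clamp_potential`` and the rim flux is the measured clamp current.
    """

    theta_a: float
    mode: str = CURRENT_CLAMP
    clamp_potential: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_a < math.pi:
            raise ValueError(f"theta_a must lie in (0, pi), got {self.theta_a}")
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValueError(
                f"mode must be {CURRENT_CLAMP!r} or {VOLTAGE_CLAMP!r}, got {self.mode!r}"
            )


@dataclass(frozen=True)
class StimulusProtocol:
    """Current stimulus.

    kind : "step" (on from t_on), "pulse" (on during [t_on, t_off)) or "off".
    amplitude : total injected current [A].
    site : "pipette_cap" (through the electrode, Neumann rim flux) or
           "south_band" (distributed over theta in [pi - band_halfwidth, pi]).
    """

    kind: str = "step"
    amplitude: float = 0.0
    t_on: float = 0.0
    t_off: float = math.inf
    site: str = "pipette_cap"
    band_halfwidth: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("step", "pulse", "off"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.site not in ("pipette_cap", "south_band"):
            raise ValueError(f"unknown stimulus site {self.site!r}")
        if not math.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")
        if self.kind == "pulse" and not self.t_on < self.t_off:
            raise ValueError("pulse requires t_on < t_off")

    def current(self, t: float) -> float:
        """Injected current at time ``t`` [A]."""
        if self.kind == "off":
            return 0.0
        if self.kind == "step":
            return self.amplitude if t >= self.t_on else 0.0
        return self.amplitude if self.t_on <= t < self.t_off else 0.0

    def switch_times(self) -> list[float]:
        """Times at which the stimulus changes value (for exact integrators)."""
        if self.kind == "off":
            return []
        if self.kind == "step":
            return [self.t_on]
        return [self.t_on, self.t_off]


@dataclass(frozen=True)
class NuRoots:
    """Legendre degrees nu+- of the steady-state solution.

    The pair always satisfies nu+ + nu- = -1.  For rho/lambda <= 1/2 both
    are real; beyond that they form the complex-conjugate pair
    -1/2 +- i mu (conical functions).
    """

    nu_plus: complex
    nu_minus: complex = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nu_minus is None:
            object.__setattr__(self, "nu_minus", -1 - self.nu_plus)
        if abs(self.nu_plus + self.nu_minus + 1) > 1e-12:
            raise ValueError("nu_plus + nu_minus must equal -1")

    @property
    def is_real(self) -> bool:
        return abs(self.nu_plus.imag) == 0


def membrane_time_constant(params: MembraneParams) -> float:
    """tau = r_m * c_m [s]."""
    return params.tau


def electrotonic_length_sphere(params: MembraneParams, geom: SphereGeometry) -> float:
    """lambda = sqrt(r_m d / r_i) [m] for the thin spherical shell."""
    return math.sqrt(params.r_m * geom.d / params.r_i)


def electrotonic_length_cable(params: MembraneParams, geom: CableGeometry) -> float:
    """lambda_cable = sqrt(d_cable r_m / (4 r_i)) [m]."""
    return math.sqrt(geom.d_cable * params.r_m / (4.0 * params.r_i))


def nu_roots(rho: float, lam: float) -> NuRoots:
    """Roots nu+- = -1/2 +- (1/2) sqrt(1 - 4 rho^2/lambda^2).

    The principal square root is taken, so for rho/lambda > 1/2 the pair is
    the complex conjugates -1/2 +- i mu with mu = sqrt(4 rho^2/lambda^2 - 1)/2.
    """
    if not (rho > 0 and lam > 0):
        raise ValueError("rho and lam must be positive")
    radicand = 1.0 - 4.0 * (rho / lam) ** 2
    root = cmath.sqrt(radicand)
    nu_plus = (-1.0 + root) / 2.0
    if abs(nu_plus.imag) == 0:
        nu_plus = complex(nu_plus.real, 0.0)
    return NuRoots(nu_plus=nu_plus, nu_minus=(-1.0 - root) / 2.0)


def pipette_half_angle(pipette_diameter: float, rho: float) -> float:
    """Cap half-angle from the pipette tip diameter (chord convention).

    theta_a = arcsin(r_pip / rho); a 2 µm pipette on a 40 µm cell gives
    theta_a = 0.0250.  Differences from the arc-length convention are
    O(theta_a^3).
    """
    if not rho > 0:
        raise ValueError("rho must be positive")
    if pipette_diameter < 0:
        raise ValueError("pipette diameter must be non-negative")
    ratio = pipette_diameter / (2.0 * rho)
    if ratio >= 1.0:
        raise ValueError(
            f"pipette diameter {pipette_diameter:g} m must be smaller than the "
            f"sphere diameter {2 * rho:g} m"
        )
    return math.asin(ratio)
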
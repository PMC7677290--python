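"""YAML configuration loading and writing.

A config is a flat mapping with unit-suffixed values, e.g.::

    c_m: 1 uF/cm^2
    r_m: 100 kOhm.cm^2
    r_i: 100 Ohm.cm
    rho: 40 um
    d: 0.5 um
    pipette_diameter: 2 um     # or theta_a: 0.025
    mode: current_clamp
    stimulus:
      kind: step
      amplitude: 100 pA
      site: pipette_cap

Unknown keys are rejected, missing or non-positive parameters raise a
single validation error listing every offending key.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import yaml

from .params import (
    CableGeometry,
    ElectrodeConfig,
    MembraneParams,
    SphereGeometry,
    StimulusProtocol,
    pipette_half_angle,
)
from .units import UnitError, from_si, parse_quantity

__all__ = ["load_config", "loads_config", "dump_config", "ConfigError", "adipocyte_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent configuration file."""


_TOP_KEYS = {
    "c_m", "r_m", "r_i", "E",
    "rho", "d",                      # sphere geometry
    "d_cable", "L",                  # cable geometry
    "theta_a", "pipette_diameter",
    "mode", "clamp_potential",
    "stimulus",
}
_STIM_KEYS = {"kind", "amplitude", "t_on", "t_off", "site", "band_halfwidth"}


def _get(raw: dict, key: str, errors: list[str], expect: str, default=None):
    if key not in raw:
        if default is not None:
            return default
        errors.append(f"missing required key {key!r}")
        return None
    try:
        return parse_quantity(raw[key], expect=expect)
    except (UnitError, ValueError) as exc:
        errors.append(f"{key}: {exc}")
        return None


def loads_config(raw: dict[str, Any]):
    """Validate a raw mapping; return (membrane, geometry, electrode, stimulus).

    ``geometry`` is a :class:`SphereGeometry` when ``rho``/``d`` are given,
    a :class:`CableGeometry` when ``d_cable``/``L`` are given.
    """
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}")

    errors: list[str] = []
    c_m = _get(raw, "c_m", errors, "capacitance_area")
    r_m = _get(raw, "r_m", errors, "resistance_area")
    r_i = _get(raw, "r_i", errors, "resistivity")
    E = _get(raw, "E", errors, "voltage", default=0.0)

    is_sphere = "rho" in raw or "d" in raw
    is_cable = "d_cable" in raw or "L" in raw
    if is_sphere == is_cable:
        raise ConfigError("exactly one geometry required: rho/d (sphere) or d_cable/L (cable)")

    membrane = None
    if not errors:
        try:
            membrane = MembraneParams(c_m=c_m, r_m=r_m, r_i=r_i, E=E)
        except ValueError as exc:
            errors.append(str(exc))

    geometry = None
    if is_sphere:
        rho = _get(raw, "rho", errors, "length")
        d = _get(raw, "d", errors, "length")
        if rho is not None and d is not None:
            try:
                geometry = SphereGeometry(rho=rho, d=d)
            except ValueError as exc:
                errors.append(str(exc))
    else:
        d_cable = _get(raw, "d_cable", errors, "length")
        L = math.inf if str(raw.get("L", "")).strip() in ("inf", "infinite") else _get(
            raw, "L", errors, "length")
        if d_cable is not None and L is not None:
            try:
                geometry = CableGeometry(d_cable=d_cable, L=L)
            except ValueError as exc:
                errors.append(str(exc))

    theta_a = None
    if "theta_a" in raw and "pipette_diameter" in raw:
        errors.append("give either theta_a or pipette_diameter, not both")
    elif "theta_a" in raw:
        theta_a = _get(raw, "theta_a", errors, "angle")
    elif "pipette_diameter" in raw and is_sphere and geometry is not None:
        diam = _get(raw, "pipette_diameter", errors, "length")
        if diam is not None:
            try:
                theta_a = pipette_half_angle(diam, geometry.rho)
            except ValueError as exc:
                errors.append(f"pipette_diameter: {exc}")
    elif is_sphere:
        errors.append("missing required key 'theta_a' or 'pipette_diameter'")

    mode = raw.get("mode", "current_clamp")
    clamp_potential = _get(raw, "clamp_potential", errors, "voltage", default=0.0)
    electrode = None
    if theta_a is not None or not is_sphere:
        try:
            electrode = ElectrodeConfig(
                theta_a=theta_a if theta_a is not None else 0.1,
                mode=mode,
                clamp_potential=clamp_potential,
            )
        except ValueError as exc:
            errors.append(str(exc))

    stim_raw = raw.get("stimulus", {}) or {}
    if not isinstance(stim_raw, dict):
        errors.append("stimulus must be a mapping")
        stim_raw = {}
    unknown = set(stim_raw) - _STIM_KEYS
    if unknown:
        errors.append(f"unknown stimulus keys: {sorted(unknown)}")
    stimulus = None
    if not errors:
        try:
            stimulus = StimulusProtocol(
                kind=stim_raw.get("kind", "off"),
                amplitude=parse_quantity(stim_raw.get("amplitude", 0.0), expect="current")
                if "amplitude" in stim_raw else 0.0,
                t_on=parse_quantity(stim_raw.get("t_on", 0.0), expect="time")
                if "t_on" in stim_raw else 0.0,
                t_off=parse_quantity(stim_raw["t_off"], expect="time")
                if "t_off" in stim_raw else math.inf,
                site=stim_raw.get("site", "pipette_cap"),
                band_halfwidth=parse_quantity(stim_raw.get("band_halfwidth", 0.1), expect="angle"),
            )
        except (UnitError, ValueError) as exc:
            errors.append(f"stimulus: {exc}")

    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    return membrane, geometry, electrode, stimulus


def load_config(path: str | Path):
    """Read and validate a YAML config file; see :func:`loads_config`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return loads_config(raw)


def dump_config(membrane, geometry, electrode, stimulus, path: str | Path) -> None:
    """Write objects back to YAML in conventional units (round-trip exact)."""
    out: dict[str, Any] = {
        "c_m": f"{from_si(membrane.c_m, 'uF/cm^2'):.17g} uF/cm^2",
        "r_m": f"{from_si(membrane.r_m, 'kOhm.cm^2'):.17g} kOhm.cm^2",
        "r_i": f"{from_si(membrane.r_i, 'Ohm.cm'):.17g} Ohm.cm",
        "E": f"{from_si(membrane.E, 'mV'):.17g} mV",
    }
    if isinstance(geometry, SphereGeometry):
        out["rho"] = f"{from_si(geometry.rho, 'um'):.17g} um"
        out["d"] = f"{from_si(geometry.d, 'um'):.17g} um"
    else:
        out["d_cable"] = f"{from_si(geometry.d_cable, 'um'):.17g} um"
        out["L"] = "inf" if geometry.is_infinite else f"{from_si(geometry.L, 'um'):.17g} um"
    if electrode is not None:
        out["theta_a"] = f"{electrode.theta_a:.17g} rad"
        out["mode"] = electrode.mode
        out["clamp_potential"] = f"{from_si(electrode.clamp_potential, 'mV'):.17g} mV"
    if stimulus is not None:
        stim: dict[str, Any] = {
            "kind": stimulus.kind,
            "amplitude": f"{from_si(stimulus.amplitude, 'pA'):.17g} pA",
            "site": stimulus.site,
            "band_halfwidth": f"{stimulus.band_halfwidth:.17g} rad",
        }
        if stimulus.kind != "off":
            stim["t_on"] = f"{from_si(stimulus.t_on, 'ms'):.17g} ms"
        if stimulus.kind == "pulse":
            stim["t_off"] = f"{from_si(stimulus.t_off, 'ms'):.17g} ms"
        out["stimulus"] = stim
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def adipocyte_config() -> dict[str, Any]:
    """The canonical white-adipocyte parameter set as a raw config mapping.

    Radius 40 µm, shell 0.5 µm, c_m 1 µF/cm², r_m 100 kΩ·cm², r_i 100 Ω·cm,
    2 µm pipette (theta_a = 0.025); step current of 100 pA through the cap.
    """
    return {
        "c_m": "1 uF/cm^2",
        "r_m": "100 kOhm.cm^2",
        "r_i": "100 Ohm.cm",
        "rho": "40 um",
        "d": "0.5 um",
        "pipette_diameter": "2 um",
        "mode": "current_clamp",
        "stimulus": {"kind": "step", "amplitude": "100 pA", "site": "pipette_cap"},
    }
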
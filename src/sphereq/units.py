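"""Unit handling for electrophysiological quantities.

The internal unit system is SI throughout (metres, seconds, ohms, farads,
amperes, volts).  Configuration files and the conventional electrophysiology
literature mix µm, Ω·cm, kΩ·cm², µF/cm², ms and pA; every conversion factor
here is an exact power of ten so that converting to SI and back reproduces
the input to machine precision.

A quantity in a config file is a string ``"<number> <unit>"``, e.g.
``"100 kOhm.cm^2"`` or ``"40 um"``.  Unit names are ASCII: ``Ohm`` for Ω,
``u`` for µ; ``.`` denotes a product and ``^`` a power, ``/`` a quotient.
"""

from __future__ import annotations

from fractions import Fraction

__all__ = ["UNIT_TABLE", "parse_quantity", "to_si", "from_si", "UnitError"]


class UnitError(ValueError):
    """Raised for unknown units or dimension mismatches."""


# unit -> (dimension tag, exact factor to SI)
UNIT_TABLE: dict[str, tuple[str, Fraction]] = {
    # length
    "m": ("length", Fraction(1)),
    "cm": ("length", Fraction(1, 10**2)),
    "mm": ("length", Fraction(1, 10**3)),
    "um": ("length", Fraction(1, 10**6)),
    "nm": ("length", Fraction(1, 10**9)),
    # time
    "s": ("time", Fraction(1)),
    "ms": ("time", Fraction(1, 10**3)),
    "us": ("time", Fraction(1, 10**6)),
    # specific membrane resistance (resistance x area)
    "Ohm.m^2": ("resistance_area", Fraction(1)),
    "Ohm.cm^2": ("resistance_area", Fraction(1, 10**4)),
    "kOhm.cm^2": ("resistance_area", Fraction(10**3, 10**4)),
    "MOhm.cm^2": ("resistance_area", Fraction(10**6, 10**4)),
    # intracellular resistivity (resistance x length)
    "Ohm.m": ("resistivity", Fraction(1)),
    "Ohm.cm": ("resistivity", Fraction(1, 10**2)),
    "kOhm.cm": ("resistivity", Fraction(10)),
    # specific capacitance (capacitance / area)
    "F/m^2": ("capacitance_area", Fraction(1)),
    "uF/cm^2": ("capacitance_area", Fraction(1, 10**2)),
    # current
    "A": ("current", Fraction(1)),
    "mA": ("current", Fraction(1, 10**3)),
    "uA": ("current", Fraction(1, 10**6)),
    "nA": ("current", Fraction(1, 10**9)),
    "pA": ("current", Fraction(1, 10**12)),
    # voltage
    "V": ("voltage", Fraction(1)),
    "mV": ("voltage", Fraction(1, 10**3)),
    # resistance
    "Ohm": ("resistance", Fraction(1)),
    "MOhm": ("resistance", Fraction(10**6)),
    "GOhm": ("resistance", Fraction(10**9)),
    # plain angle / dimensionless
    "rad": ("angle", Fraction(1)),
}


def to_si(value: float, unit: str, expect: str | None = None) -> float:
    """Convert ``value`` expressed in ``unit`` to SI.

    ``expect`` optionally names the required dimension tag and raises
    :class:`UnitError` on mismatch.
    """
    try:
        dim, factor = UNIT_TABLE[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}; known units: {sorted(UNIT_TABLE)}")
    if expect is not None and dim != expect:
        raise UnitError(f"unit {unit!r} has dimension {dim!r}, expected {expect!r}")
    return float(value) * float(factor)


def from_si(value: float, unit: str) -> float:
    """Convert an SI ``value`` to the named unit (exact reciprocal factor)."""
    try:
        _, factor = UNIT_TABLE[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}")
    return float(Fraction(1) / factor) * float(value)


def parse_quantity(text: str | float | int, expect: str | None = None) -> float:
    """Parse ``"<number> <unit>"`` into an SI float.

    Bare numbers are accepted only when ``expect`` is ``"angle"`` or ``None``
    (dimensionless context); everything dimensional must carry a unit.
    """
    if isinstance(text, (int, float)):
        if expect in (None, "angle"):
            return float(text)
        raise UnitError(f"missing unit on value {text!r} (expected {expect})")
    parts = str(text).split()
    if len(parts) == 1:
        if expect in (None, "angle"):
            return float(parts[0])
        raise UnitError(f"missing unit in {text!r} (expected {expect})")
    if len(parts) != 2:
        raise UnitError(f"cannot parse quantity {text!r}; expected '<number> <unit>'")
    value, unit = parts
    return to_si(float(value), unit, expect=expect)
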
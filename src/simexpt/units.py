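"""Unit registry for experiment files.

Canonical internal frame: concentration in millimolar, time in seconds,
voltage in millivolts, current density in microamps per cm^2.  Conversion is
a single multiplicative factor per unit, so to-canonical followed by
from-canonical is exact to floating-point rounding.
"""

from __future__ import annotations

__all__ = ["UnitError", "to_canonical", "from_canonical", "kind_of",
           "SUPPORTED_UNITS"]


class UnitError(ValueError):
    pass


# unit -> (kind, factor to canonical)
SUPPORTED_UNITS: dict[str, tuple[str, float]] = {
    # concentration -> mM
    "M": ("conc", 1e3),
    "mM": ("conc", 1.0),
    "uM": ("conc", 1e-3),
    "nM": ("conc", 1e-6),
    "pM": ("conc", 1e-9),
    # time -> s
    "s": ("time", 1.0),
    "ms": ("time", 1e-3),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    # voltage -> mV
    "mV": ("volt", 1.0),
    # current density -> uA/cm^2
    "uA": ("current", 1.0),
    "nA": ("current", 1e-3),
    "pA": ("current", 1e-6),
    # dimensionless passthrough (e.g. fold-change readouts)
    "none": ("dimensionless", 1.0),
}


def kind_of(unit: str) -> str:
    try:
        return SUPPORTED_UNITS[unit][0]
    except KeyError:
        raise UnitError(f"unsupported unit {unit!r}; supported: "
                        f"{sorted(SUPPORTED_UNITS)}") from None


def to_canonical(value: float, unit: str) -> float:
    kind_of(unit)
    return value * SUPPORTED_UNITS[unit][1]


def from_canonical(value: float, unit: str) -> float:
    kind_of(unit)
    return value / SUPPORTED_UNITS[unit][1]
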
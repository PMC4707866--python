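"""Unit-tagged quantity parsing.

Internal units are fixed throughout the package: concentrations in µM,
lengths in m, times in s, pressures in Pa, permeability in m², mass
concentration in g/l (= mg/ml), diffusivity in m²/s.  Configuration files
carry explicit unit suffixes ("50 nM", "2.5 mm", "1 Pa"); this module is the
single place they are converted, because the model mixes nm/mm/µM/Pa scales
and silent unit slips are the dominant failure mode of this kind of code.
"""

from __future__ import annotations

import re

from .errors import ConfigError

#: factor tables: value_in_internal = value * factor
_CONCENTRATION = {"M": 1e6, "mM": 1e3, "uM": 1.0, "µM": 1.0, "nM": 1e-3, "pM": 1e-6}
_LENGTH = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}
_TIME = {"s": 1.0, "min": 60.0, "h": 3600.0, "ms": 1e-3}
_PRESSURE = {"Pa": 1.0, "kPa": 1e3, "mmHg": 133.322}
_MASS_CONC = {"g/l": 1.0, "g/L": 1.0, "mg/ml": 1.0, "mg/mL": 1.0, "g/ml": 1e3, "kg/m3": 1.0, "ug/ml": 1e-3}
_DIFFUSIVITY = {"m2/s": 1.0, "m^2/s": 1.0, "cm2/s": 1e-4, "um2/s": 1e-12}
_PERMEABILITY = {"m2": 1.0, "m^2": 1.0, "cm2": 1e-4, "darcy": 9.869233e-13}
_VELOCITY = {"m/s": 1.0, "mm/s": 1e-3, "um/s": 1e-6, "um/min": 1e-6 / 60.0, "µm/min": 1e-6 / 60.0}

DIMENSIONS = {
    "concentration": _CONCENTRATION,
    "length": _LENGTH,
    "time": _TIME,
    "pressure": _PRESSURE,
    "mass_concentration": _MASS_CONC,
    "diffusivity": _DIFFUSIVITY,
    "permeability": _PERMEABILITY,
    "velocity": _VELOCITY,
}

_QUANTITY_RE = re.compile(r"^\s*([+-]?[0-9.]+(?:[eE][+-]?[0-9]+)?)\s*([^\s]+)\s*$")


def parse_quantity(value, dimension: str, *, key: str = "") -> float:
    """Convert a config value to internal units.

    ``value`` may be a bare number (assumed already internal) or a string
    with a unit suffix, e.g. ``"50 nM"``.  ``dimension`` selects the factor
    table.  Raises :class:`ConfigError` naming the expected unit family on a
    mismatch.
    """
    table = DIMENSIONS.get(dimension)
    if table is None:
        raise ConfigError(f"unknown dimension {dimension!r}")
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, str):
        raise ConfigError(f"{key or 'value'}: expected number or 'number unit' string, got {value!r}")
    m = _QUANTITY_RE.match(value)
    if not m:
        raise ConfigError(f"{key or 'value'}: cannot parse quantity {value!r}")
    num, unit = m.groups()
    if unit not in table:
        raise ConfigError(
            f"{key or 'value'}: unit {unit!r} is not a {dimension} unit "
            f"(expected one of {sorted(table)})"
        )
    return float(num) * table[unit]


def format_quantity(value: float, dimension: str) -> str:
    """Render an internal-unit value with its canonical unit suffix."""
    canonical = {
        "concentration": "uM",
        "length": "m",
        "time": "s",
        "pressure": "Pa",
        "mass_concentration": "g/l",
        "diffusivity": "m2/s",
        "permeability": "m2",
        "velocity": "m/s",
    }[dimension]
    return f"{value:g} {canonical}"
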
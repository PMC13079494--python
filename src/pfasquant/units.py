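"""Exact decimal unit conversions for the closed unit set used by the pipeline.

All supported units within a dimension differ by powers of ten, so the
scaling itself is exact rational arithmetic. The conversion is
type-preserving:

* ``Decimal`` and ``Fraction`` inputs are scaled exactly — round-tripping
  through any supported pair is the identity, bit for bit;
* ``float`` inputs return the correctly rounded (single-rounding) float of
  the exact result. A float round-trip can land one ulp off in rare cases
  — that is a property of binary floating point, not of the scaling —
  so code that needs exact reversibility passes ``Decimal``.
"""

from __future__ import annotations

from decimal import Decimal
from fractions import Fraction

from .model import UnitError

# (dimension, power of ten relative to the dimension's base unit)
_UNITS: dict[str, tuple[str, int]] = {
    # concentration, base ng/L
    "ng/L": ("conc", 0),
    "µg/L": ("conc", 3),
    "ug/L": ("conc", 3),
    "mg/L": ("conc", 6),
    "ng/mL": ("conc", 3),  # ng/mL == µg/L
    # flow
    "L/day": ("flow", 0),
    # mass rate, base ng/day
    "ng/day": ("rate", 0),
    "µg/day": ("rate", 3),
    "ug/day": ("rate", 3),
    "mg/day": ("rate", 6),
}


def convert_units(value, from_unit: str, to_unit: str):
    """Convert ``value`` between two supported units of the same dimension."""
    try:
        dim_from, p_from = _UNITS[from_unit]
        dim_to, p_to = _UNITS[to_unit]
    except KeyError as exc:
        raise UnitError(f"unsupported unit {exc.args[0]!r}") from None
    if dim_from != dim_to:
        raise UnitError(f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})")
    power = p_from - p_to
    if isinstance(value, Decimal):
        return value.scaleb(power)
    if isinstance(value, Fraction):
        return value * Fraction(10) ** power
    return float(Fraction(value) * Fraction(10) ** power)
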
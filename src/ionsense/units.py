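"""Concentration unit handling.

All concentrations are stored internally in molar (M). Config files and
CSV tables carry explicit unit tags; this module converts them.
"""

from __future__ import annotations

_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def to_molar(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to molar."""
    try:
        factor = _FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_FACTORS)}"
        ) from None
    return value * factor


def from_molar(value: float, unit: str) -> float:
    """Convert a molar ``value`` to ``unit``."""
    try:
        factor = _FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_FACTORS)}"
        ) from None
    return value / factor
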
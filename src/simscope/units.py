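"""Length-unit handling.

All internal lengths are nanometres (floats; step arithmetic stays exact at
integer-nm scale).  User-facing strings accept ``nm``, ``um``/``µm`` and ``mm``
suffixes.
"""

from __future__ import annotations

import re

_UNIT_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "mm": 1e6}

_LENGTH_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*(nm|um|µm|mm)\s*$")


def parse_length_nm(value: str | int | float) -> float:
    """Parse a length with a unit suffix into nanometres.

    Bare numbers are rejected: a length without a unit is ambiguous.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        raise ValueError(
            f"unit-less length {value!r}: lengths must carry a unit suffix "
            "(nm, um, mm), e.g. '500nm' or '10um'"
        )
    m = _LENGTH_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse length {value!r}; expected e.g. '500nm', '10um', '1.5mm'")
    return float(m.group(1)) * _UNIT_NM[m.group(2)]


def format_length_nm(nm: float) -> str:
    """Render a nanometre length with a compact unit."""
    if abs(nm) >= 1e6:
        return f"{nm / 1e6:g}mm"
    if abs(nm) >= 1e3:
        return f"{nm / 1e3:g}um"
    return f"{nm:g}nm"
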
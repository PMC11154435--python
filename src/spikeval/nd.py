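"""The "not detectable" sentinel.

Chromatographic tables report ``nd`` when a peak's signal-to-noise ratio
falls below 3. This is a censoring state: it is *not* zero (the analyte may
be present below the detection capability) and it is not a missing cell
(the injection was made and inspected). The sentinel therefore has to be
distinct from both ``0.0`` and ``None``/``NaN``, and it must propagate
through every ratio and mean that touches it.
"""

from __future__ import annotations

from typing import Any

__all__ = ["ND", "NDType", "is_nd", "coerce_area"]


class NDType:
    """Singleton marker for a censored (not-detectable) measurement."""

    _instance: "NDType | None" = None

    def __new__(cls) -> "NDType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "nd"

    def __bool__(self) -> bool:
        # nd is falsy so `value or default` style code fails loudly in
        # arithmetic rather than silently treating nd as a number.
        return False

    def __reduce__(self):
        return (NDType, ())


ND = NDType()


def is_nd(value: Any) -> bool:
    return isinstance(value, NDType)


def coerce_area(raw: Any) -> "float | NDType | None":
    """Parse one area cell: number, the literal token ``nd`` (any case),
    or blank/None for a genuinely missing cell.

    Raises ``ValueError`` for anything else (malformed numeric text).
    """
    if raw is None or is_nd(raw):
        return raw
    if isinstance(raw, float) and raw != raw:  # NaN from pandas = blank cell
        return None
    if isinstance(raw, (int, float)):
        value = float(raw)
    else:
        text = str(raw).strip()
        if text == "":
            return None
        if text.lower() == "nd":
            return ND
        value = float(text)  # ValueError surfaces to the caller
    if value < 0:
        raise ValueError(f"negative peak area: {value!r}")
    return value
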
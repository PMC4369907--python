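"""Experimental design constants and sample-code parsing.

The study design is 2 rice lines x 2 conditions x 3 biological
replicates = 12 libraries.  Sample codes follow the convention
``{line}{condition}{replicate}``: the first letter is ``S`` for the
heat-sensitive line (HS) or ``T`` for the heat-tolerant line (HT); the
second is ``C`` for control (25 C nights) or ``T`` for treatment (38 C
nights); the digit is the biological replicate.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

LINES = ("HS", "HT")
CONDITIONS = ("control", "treatment")

#: The 12 sample codes in canonical column order.
SAMPLES = tuple(
    f"{line}{cond}{rep}" for line in "ST" for cond in "CT" for rep in (1, 2, 3)
)

_LINE_CODE = {"S": "HS", "T": "HT"}
_COND_CODE = {"C": "control", "T": "treatment"}


def line_of(sample: str) -> str:
    """Map a sample code such as ``SC1`` to its line label (``HS``/``HT``)."""
    try:
        return _LINE_CODE[sample[0]]
    except (KeyError, IndexError):
        raise ValueError(f"unrecognised sample code: {sample!r}") from None


def condition_of(sample: str) -> str:
    """Map a sample code such as ``SC1`` to ``control`` or ``treatment``."""
    try:
        return _COND_CODE[sample[1]]
    except (KeyError, IndexError):
        raise ValueError(f"unrecognised sample code: {sample!r}") from None


def samples_for(line: str, condition: str) -> list[str]:
    """Sample codes for one line x condition cell, replicate order."""
    if line not in LINES:
        raise ValueError(f"line must be one of {LINES}, got {line!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    return [s for s in SAMPLES if line_of(s) == line and condition_of(s) == condition]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used in printed tables.

    Python's builtin ``round`` is banker's rounding; summary tables in the
    field are conventionally printed with 0.5 rounding up in magnitude.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, total: float, ndigits: int = 2) -> float:
    """``100 * part / total`` rounded half-up to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * part / total, ndigits)
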
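"""Display rounding helpers.

All model arithmetic is carried out on unrounded floats; these helpers are
used only at the reporting layer. Rounding is *half up* (2888.5 -> 2889),
not banker's rounding, which is what the published tables use.
"""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, ties away from zero upward."""
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


def round_to_int(x: float) -> int:
    """Round half up to the nearest integer."""
    return int(math.floor(x + 0.5))


def round_to_thousand(x: float) -> int:
    """Round half up to the nearest $1000 (break-even reporting granularity)."""
    return int(math.floor(x / 1000.0 + 0.5)) * 1000
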
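"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves rounded up.

    Python's built-in ``round`` is banker's rounding; percentage tables in
    clinical reports conventionally round half-up.
    """
    return int(math.floor(x + 0.5))
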
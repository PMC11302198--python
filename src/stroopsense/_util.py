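"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer, with .5 rounding away from zero toward +inf.

    Used everywhere a fractional count (planted features, discarded points,
    per-class test-set sizes) must become an integer, so that all counting
    rules in the package agree.
    """
    return int(math.floor(x + 0.5))
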
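"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def spawn_seed(master_seed: int, *keys: int) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and keys."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *[int(k) & 0x7FFFFFFF for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))
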
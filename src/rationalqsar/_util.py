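"""Shared numeric and randomness helpers."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's built-in ``round`` uses banker's rounding, which turns 90.65
    into 90.6; reported percentages here follow the half-up convention
    (90.65 -> 90.7).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def substream(master_seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from one master seed.

    Every stage of the pipeline draws from its own substream so that adding
    or re-ordering stages never perturbs the randomness of the others.
    """
    digest = hashlib.sha256(f"{int(master_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream(master_seed, name))
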
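"""Shared helpers: seeded substreams and report rounding."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from a single master seed.

    Every source of randomness in the package draws from one of these, so
    the master seed alone pins down every simulated quantity while the
    streams for different purposes stay statistically independent.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with halves away from zero (report convention, not banker's)."""
    factor = 10.0**ndigits
    scaled = x * factor
    return float(np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor)
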
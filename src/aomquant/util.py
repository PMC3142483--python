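"""Unit constants, rounding helpers and deterministic sub-seeding."""

from __future__ import annotations

import zlib

import numpy as np

#: cubic micrometres per millilitre (1 ml = 1 cm^3 = 1e12 um^3)
UM3_PER_ML = 1.0e12

#: mean Gregorian month length, used to express doubling times in months
DAYS_PER_MONTH = 30.44

#: assumed diameter of a free-living ANME/SRB cell, um
SINGLE_CELL_DIAMETER_UM = 0.45


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if sig < 1:
        raise ValueError("sig must be >= 1")
    x = float(x)
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Return a generator for a named stream derived from one global seed.

    Streams are keyed by a CRC32 of the stream name, so adding a new
    simulation stage never perturbs the draws of existing stages.
    """
    key = zlib.crc32(stream.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
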
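"""Shared helpers: seeded RNG streams and interval arithmetic."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def child_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from a single master seed.

    The child stream is keyed on the stage name so that adding or reordering
    stages does not perturb the draws of unrelated stages.
    """
    stage_key = zlib.crc32(stage.encode("utf-8")) & MAX_SEED
    ss = np.random.SeedSequence([int(master_seed) & MAX_SEED, stage_key])
    return np.random.default_rng(ss)


def interval_length(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive interval."""
    if end < start:
        raise ValueError(f"end < start: [{start}, {end}]")
    return end - start + 1


def intersection_length(s1: int, e1: int, s2: int, e2: int) -> int:
    """Overlap in bp between two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to a number of significant figures (for display only)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + digits - 1)
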
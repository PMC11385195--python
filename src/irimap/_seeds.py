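"""Deterministic per-stage seed derivation.

A single master seed drives the whole pipeline; each stage mixes its name
into a :class:`numpy.random.SeedSequence` so stages are independent yet
reproducible, and inserting a new stage never reshuffles the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from ``master``."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master: int, stage: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for one named pipeline stage."""
    return np.random.default_rng(derive_seed(master, stage))
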
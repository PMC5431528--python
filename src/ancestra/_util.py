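"""Shared helpers: deterministic seed fan-out and small numeric guards."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage integer seed from one global seed.

    The stage name is hashed with CRC-32 so that reruns of a single stage
    reproduce its stream regardless of which other stages ran before it.
    """
    return int((int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))
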
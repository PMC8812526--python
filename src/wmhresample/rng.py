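"""Named, reproducible random substreams.

A single master seed drives the whole experiment.  Every stage (cohort
generation, each participant, each training draw) pulls its own generator
from a *named* substream, so adding participants or draws never perturbs
the random numbers consumed by earlier ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_rng"]


def _hash_token(token: object) -> int:
    """Map a label (str or int) to a stable 32-bit integer."""
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    return zlib.crc32(str(token).encode("utf-8"))


def substream(master_seed: int, *tokens: object) -> np.random.SeedSequence:
    """Derive a named SeedSequence from the master seed.

    The token path (e.g. ``("participant", 17, "BL")``) is hashed into the
    entropy pool, so distinct paths give statistically independent streams
    and identical paths always give the same stream.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_hash_token(t) for t in tokens]
    return np.random.SeedSequence(entropy)


def spawn_rng(master_seed: int, *tokens: object) -> np.random.Generator:
    """Generator on the named substream."""
    return np.random.default_rng(substream(master_seed, *tokens))
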
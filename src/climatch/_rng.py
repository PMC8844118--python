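"""Deterministic seed substreams.

A single master seed drives every stochastic stage of the pipeline. Each
stage (and each replicate within a stage) derives its own independent
stream by hashing a tuple of string tokens into a ``SeedSequence`` spawn
key, so any stage can be re-run in isolation and reproduce its draws
bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _token_key(token: object) -> int:
    return zlib.crc32(str(token).encode("utf-8"))


def substream(master_seed: int, *tokens: object) -> np.random.Generator:
    """Return an independent ``Generator`` for (master_seed, *tokens)."""
    key = tuple(_token_key(t) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=key))


def spawn_seed(master_seed: int, *tokens: object) -> int:
    """A plain integer seed (< 2**31) derived from the substream, for APIs
    that take ``random_state`` rather than a Generator."""
    return int(substream(master_seed, *tokens).integers(0, 2**31 - 1))
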
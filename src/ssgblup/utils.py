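"""Shared helpers: named random substreams and small numeric utilities."""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "derive_seed", "symmetrize"]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a master seed.

    Every source of randomness in the pipeline (simulation, MCMC,
    cross-validation partitioning, ...) draws from its own named substream,
    so changing how one consumer uses randomness never perturbs the others.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def derive_seed(seed: int, name: str) -> int:
    """A deterministic 31-bit integer seed for the named substream."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(zlib.crc32(name.encode("utf-8")),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def symmetrize(m: np.ndarray) -> np.ndarray:
    """Average a nearly symmetric matrix with its transpose."""
    return (m + m.T) / 2.0
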
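"""Deterministic fan-out of one global seed into independent child streams.

Every stochastic component in the package draws its generator from
:func:`child_rng` so that a single integer seed fixes the whole pipeline.
String key components are hashed with CRC-32, which is stable across
processes and platforms (unlike :func:`hash`).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def _key_to_ints(key: tuple) -> tuple[int, ...]:
    out = []
    for part in key:
        if isinstance(part, (int, np.integer)):
            out.append(int(part) & 0xFFFFFFFF)
        elif isinstance(part, str):
            out.append(zlib.crc32(part.encode("utf-8")))
        else:
            raise TypeError(f"seed key components must be int or str, got {type(part)!r}")
    return tuple(out)


def child_seed_sequence(seed: int, *key) -> np.random.SeedSequence:
    """SeedSequence for the child stream identified by ``key`` under ``seed``."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    return np.random.SeedSequence(entropy=int(seed), spawn_key=_key_to_ints(key))


def child_rng(seed: int, *key) -> np.random.Generator:
    """Independent, reproducible generator for the stream named by ``key``."""
    return np.random.default_rng(child_seed_sequence(seed, *key))
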
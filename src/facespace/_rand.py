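"""Seed fan-out.

One top-level integer seed is expanded into named, statistically independent
child streams (init, shuffle, data, ...) so that every experiment is exactly
reproducible while the individual consumers of randomness stay decoupled.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, *names: object) -> np.random.SeedSequence:
    """Deterministic child SeedSequence for a named stream under ``seed``."""
    parts = [int(seed) & 0x7FFFFFFF]
    parts += [zlib.crc32(str(n).encode("utf8")) & 0x7FFFFFFF for n in names]
    return np.random.SeedSequence(parts)


def child_rng(seed: int, *names: object) -> np.random.Generator:
    """Generator on the named child stream (see :func:`child_seed`)."""
    return np.random.default_rng(child_seed(seed, *names))
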
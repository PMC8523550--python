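"""Deterministic child-stream derivation from a single master seed.

Every stochastic stage in the package draws from a named child stream so that
one master seed reproduces the whole pipeline bit-for-bit while stages stay
statistically independent of each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(master: int, name: str) -> int:
    """A stable 32-bit seed for the stream called ``name``.

    Uses CRC32 of the name (not ``hash``, which is salted per process) so the
    derivation is identical across runs and machines.
    """
    return zlib.crc32(name.encode("utf-8")) ^ (int(master) & 0xFFFFFFFF)


def child_rng(master: int, name: str) -> np.random.Generator:
    """Generator for the named child stream of ``master``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master) & 0xFFFFFFFF, zlib.crc32(name.encode("utf-8"))])
    )
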
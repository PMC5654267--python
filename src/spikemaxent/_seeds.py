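"""Deterministic seed derivation.

Every stochastic operation in the package takes an integer seed. Pipelines
that need many independent streams derive them from one master seed plus a
short text tag, so that re-running a configuration reproduces every random
draw bit-for-bit while distinct operations never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed"]


def child_seed(seed: int, tag: str) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a text ``tag``.

    The derivation hashes the tag with CRC-32 and feeds both integers to
    :class:`numpy.random.SeedSequence`, so children with different tags are
    statistically independent and stable across platforms.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))
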
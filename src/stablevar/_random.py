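"""Deterministic stream splitting for all randomness in the package.

Every stochastic routine takes an integer ``seed`` and derives independent
child generators with :func:`spawn`, keyed by short string labels.  The same
(seed, labels) pair always yields the same stream, and streams with distinct
labels are statistically independent, so e.g. sorting noise and
quantification noise never share draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn"]


def _label_key(label: str | int) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def spawn(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a generator for the stream identified by ``labels`` under ``seed``.

    Labels may mix strings (CRC32-hashed) and integers (used verbatim), e.g.
    ``spawn(seed, "cohort", "high", replicate)``.
    """
    key = tuple(_label_key(lb) for lb in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
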
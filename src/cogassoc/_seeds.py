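"""Deterministic master-seed splitting.

Every stochastic stage of the pipeline draws from its own child stream,
derived from the master seed and a stage label, so stages can be re-run
or reordered without disturbing each other's randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master: int, label: str) -> int:
    """A stable 31-bit child seed for one named stage."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def child_rng(master: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, label))
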
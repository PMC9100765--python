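"""Shared plumbing: named random substreams and the package logger.

Every stochastic stage derives its own generator from the single pipeline
seed plus a stage name, so stages can be re-run or reordered without
perturbing each other's random draws.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("pleioscan")
if not logger.handlers:  # configure once; stderr, level via PLEIOSCAN verbosity
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a generator for the substream identified by ``names``.

    The stream is a pure function of (seed, names): the stage name is hashed
    (CRC32) into extra entropy words of a :class:`numpy.random.SeedSequence`.
    """
    words = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(words))


def stage_seed(seed: int, *names: str) -> int:
    """A 31-bit integer seed for APIs (sklearn) that take an int state."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
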
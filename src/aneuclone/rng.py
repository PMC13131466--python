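"""Named, reproducible random-number streams.

All stochastic stages derive their generator from a single user seed plus a
stage name, so a pipeline run is bit-reproducible and stages can be re-run
in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str = "") -> np.random.Generator:
    """Return a Generator for stage `name` derived from the master `seed`.

    The stage name is folded in through a CRC32 so distinct stages get
    statistically independent streams while the mapping stays stable across
    runs and platforms.
    """
    if name:
        ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    else:
        ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    return np.random.default_rng(ss)
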
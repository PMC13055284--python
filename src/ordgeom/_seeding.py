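"""Named substreams derived from a single master seed.

Every stochastic stage of the package draws from its own named substream so
that stages are reproducible in isolation: regenerating the count table does
not perturb, say, the NMDS restarts or the permutation test.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of master ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for libraries that want one."""
    return int(substream(seed, name).integers(2**31))
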
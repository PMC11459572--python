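"""Deterministic named substreams from one global seed.

Every stochastic stage draws from its own named substream so stages are
individually reproducible and inserting a new stage does not perturb the
others.  The substream seed is a stable hash of ``(seed, name)`` reduced
below 2**31.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream_seed(seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def substream_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(seed, name))
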
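"""Seeded random-number substreams.

Every stage of the pipeline draws from its own named substream derived from a
single pipeline seed, so e.g. changing the number of bootstrap replicates does
not perturb merge tie-breaks.
"""

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for ``name`` deterministically derived from ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def as_generator(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
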
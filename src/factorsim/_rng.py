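"""Named random substreams.

A single master seed fans out into independent, *named* substreams
(one per scores row, per (layer, factor) loading block, per-layer noise,
per-layer placement).  Because a substream's state depends only on the
master seed and its name tokens, adding a layer or a factor to a
configuration does not perturb the draws of unrelated components.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _token_entropy(token: object) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    return zlib.crc32(str(token).encode("utf-8"))


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``tokens``.

    Identical (seed, tokens) always yields an identical stream; distinct
    token tuples yield statistically independent streams (SeedSequence
    entropy mixing).
    """
    entropy = [int(seed)] + [_token_entropy(t) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))
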
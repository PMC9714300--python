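"""Shared helpers: reproducible RNG substreams."""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, *parts: str) -> np.random.Generator:
    """An independent RNG derived by stable hashing of ``(seed, *parts)``.

    Streams are invariant to the order in which other streams are drawn, so
    adding subjects, bands or comparison rows never perturbs existing ones.
    """
    key = ":".join([str(int(seed)), *map(str, parts)]).encode()
    digest = hashlib.sha256(key).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little") % (2**31))
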
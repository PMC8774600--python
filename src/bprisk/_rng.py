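"""Deterministic random-stream management.

A single user-facing seed is expanded into independent substreams, one per
(stage, key) pair, by hashing the stage labels into a second entropy word.
Adding a new stage or simulation key therefore never perturbs the draws of
existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def stream_key(*labels: object) -> int:
    """Map a label path to a stable 31-bit integer."""
    digest = hashlib.sha256("/".join(str(x) for x in labels).encode()).digest()
    return int.from_bytes(digest[:4], "little") & MAX_SEED


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``labels``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & MAX_SEED, stream_key(*labels)]))
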
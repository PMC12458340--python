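"""Seed-substream helpers.

Every stochastic stage derives its generator from a single global seed plus a
stable string key (stage name, SGB id, replicate index...). Keys are hashed
with SHA-256 so substreams are independent of dict/iteration order and stable
across platforms and Python hash randomisation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_int(key: object) -> int:
    digest = hashlib.sha256(str(key).encode("utf-8")).digest()
    # SeedSequence entropy words are uint32-sized; 4 bytes is plenty.
    return int.from_bytes(digest[:4], "big")


def child_seed(seed: int, *keys: object) -> int:
    """Deterministic sub-seed (< 2**31) for ``seed`` qualified by ``keys``."""
    h = hashlib.sha256(str(int(seed)).encode("utf-8"))
    for k in keys:
        h.update(b"/")
        h.update(str(k).encode("utf-8"))
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def substream(seed: int, *keys: object) -> np.random.Generator:
    """A Generator seeded by ``seed`` and a stable hash of ``keys``."""
    entropy = [int(seed)] + [_key_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
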
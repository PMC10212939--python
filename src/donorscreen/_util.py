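"""Shared helpers: named seeded substreams and logging setup."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_entropy(name: str) -> int:
    # stable across runs/platforms, unlike hash()
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")


def child_seed(seed: int, *names: str | int) -> int:
    """Derive a deterministic child seed < 2**31 from a master seed and names.

    One global integer seed fans out to per-stage named substreams so that
    changing the realisation of one stage never perturbs another.
    """
    entropy = [int(seed)] + [
        _name_entropy(n) if isinstance(n, str) else int(n) for n in names
    ]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """A numpy Generator on the named substream of ``seed``."""
    return np.random.default_rng(child_seed(seed, *names))
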
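"""Deterministic stream splitting.

Every stochastic operation in the package receives its own child generator
derived from a single root seed and a stage name, so that a stage can be
re-run in isolation and still produce the bytes it produced inside the full
pipeline.  The mapping from name to spawn key is a stable hash of the name,
not an enumeration order, so adding a stage never perturbs the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "child_seed"]


def _key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the child generator for ``name`` under root ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name),))
    return np.random.default_rng(ss)


def child_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for libraries that take one."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
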
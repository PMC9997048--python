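"""Seeded random-stream management.

All randomness in the package flows from one root seed through named child
streams, so that individual stages (rank coupling, noise, chain fitting,
estimator refits) can be re-run reproducibly in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["named_rng", "spawn_seed"]


def _name_key(name: str) -> int:
    # stable 32-bit hash; crc32 is deterministic across platforms/sessions
    return zlib.crc32(name.encode("utf-8"))


def spawn_seed(seed: int | None, name: str) -> np.random.SeedSequence:
    """Derive a child SeedSequence for a named stream.

    ``None`` propagates to fresh OS entropy, matching numpy semantics.
    """
    if seed is None:
        return np.random.SeedSequence()
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))


def named_rng(seed: int | None, name: str) -> np.random.Generator:
    """A Generator for the named child stream of ``seed``."""
    return np.random.default_rng(spawn_seed(seed, name))
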
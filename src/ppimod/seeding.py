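"""Deterministic per-stage random streams.

Every stochastic stage derives its own substream from the global seed and a
stage label, so adding or reordering stages never perturbs the draws of the
others, and a fixed global seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "stage_rng"]


def derive_seed(base_seed: int, label: str) -> int:
    """Stable 31-bit child seed for a named stage."""
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(base_seed: int, label: str) -> np.random.Generator:
    """Generator seeded from (base_seed, stage label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), zlib.crc32(label.encode())])
    )
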
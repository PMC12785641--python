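"""Hierarchical random streams.

One root seed governs a whole batch; structure ``k`` draws from an
independent substream derived from ``(root_seed, k)``, so the result for a
given index does not depend on batch size or on which other indices were
generated.
"""
from __future__ import annotations

import numpy as np

__all__ = ["root_rng", "structure_rng"]


def root_rng(seed: int) -> np.random.Generator:
    """Generator for batch-level draws."""
    return np.random.default_rng(np.random.SeedSequence(seed))


def structure_rng(seed: int, index: int) -> np.random.Generator:
    """Independent generator for structure ``index`` under ``seed``.

    Uses ``SeedSequence`` spawn keys, so streams for distinct indices are
    statistically independent and reproducible in isolation.
    """
    if index < 0:
        raise ValueError(f"structure index must be >= 0, got {index}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))
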
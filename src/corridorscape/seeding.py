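"""Deterministic seed derivation.

All randomness in the package flows from one master seed.  Child streams are
derived with :class:`numpy.random.SeedSequence` keyed on the master seed, a
fixed per-stage code, and any extra integer keys (e.g. the iteration index),
so every stage can be re-run independently and reproducibly.
"""

from __future__ import annotations

import numpy as np

STAGE_CODES = {
    "landscape": 1,
    "pesticide_tables": 2,
    "jitter_west": 3,
    "jitter_east": 4,
}


def child_seed_sequence(master_seed: int, stage: str, *keys: int) -> np.random.SeedSequence:
    if stage not in STAGE_CODES:
        raise KeyError(f"unknown seeding stage {stage!r}")
    return np.random.SeedSequence([int(master_seed), STAGE_CODES[stage], *map(int, keys)])


def child_rng(master_seed: int, stage: str, *keys: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for (master_seed, stage, *keys)."""
    return np.random.default_rng(child_seed_sequence(master_seed, stage, *keys))
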
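"""Seeded random-number streams.

A single user-facing seed fans out to independent per-stage streams keyed by
(seed, stage id, run index), so adding runs to one stage never perturbs the
draws of another.
"""

from __future__ import annotations

import numpy as np

# Arbitrary but fixed stage keys; changing them changes every downstream draw.
STAGE_SIMULATE = 11
STAGE_SELECT = 23
STAGE_CLUSTER = 37


def stage_rng(seed: int, stage: int, run_index: int | None = None) -> np.random.Generator:
    """Return a Generator for one (seed, stage[, run]) slot.

    The same triple always yields the same stream, on any platform.
    """
    entropy = [int(seed), int(stage)]
    if run_index is not None:
        entropy.append(int(run_index))
    return np.random.default_rng(np.random.SeedSequence(entropy))
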
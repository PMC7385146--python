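"""Seed plumbing shared by every stage.

All randomness in the package flows from one master integer seed. Each pipeline
stage derives an independent stream via ``numpy.random.SeedSequence`` spawn
keys, so adding iterations to one stage never perturbs another.
"""
from __future__ import annotations

import math

import numpy as np

# seeds handed to scikit-learn must fit in a signed 32-bit int
_SEED_MOD = 2**31 - 1

# stable spawn keys per stage
STAGE_SIMULATE = 0
STAGE_SAMPLE_KMEANS = 1
STAGE_METACLUSTER = 2
STAGE_CLASSIFIER = 3


def stage_seeds(master: int, stage: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds for a pipeline stage."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(int(stage),))
    return [int(s % _SEED_MOD) for s in ss.generate_state(n, dtype=np.uint64)]


def derive_seed(master: int, stage: int) -> int:
    return stage_seeds(master, stage, 1)[0]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
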
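"""Labeled sub-seeding: one RNG stream per artifact, all derived from one seed.

Each artifact (annotation, truth methylome, a given call table, ...) draws
from its own ``numpy`` Generator whose seed is a stable hash of the master
seed and a human-readable label.  Regenerating one artifact therefore never
perturbs another, and the same (seed, label) pair is reproducible across
sessions and platforms.
"""

import hashlib

import numpy as np


def child_seed(master_seed: int, label: str) -> int:
    """Stable 31-bit seed derived from a master seed and an artifact label."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    """Independent Generator for the artifact named ``label``."""
    return np.random.default_rng(child_seed(master_seed, label))
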
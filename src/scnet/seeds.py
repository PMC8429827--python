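"""Deterministic stage-seed derivation.

Every stochastic stage (simulation, null models, Louvain restarts,
permutation shuffles) draws its seed from a master seed plus a stage
label via SHA-256, so a single master seed fixes the whole run while
stages stay statistically independent and order-independent.
"""

from __future__ import annotations

import hashlib


def derive_stage_seeds(master_seed: int, stage_label: str) -> int:
    """Derive a stage seed in [0, 2^31) from a master seed and a label."""
    if not stage_label:
        raise ValueError("stage label must be non-empty")
    digest = hashlib.sha256(f"{int(master_seed)}:{stage_label}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)
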
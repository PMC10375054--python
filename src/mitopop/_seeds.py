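"""Deterministic derivation of per-stage seeds from one top-level seed.

Hashing the stage name means adding a new analysis stage never perturbs the
random streams of existing stages.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
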
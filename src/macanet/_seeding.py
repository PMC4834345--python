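"""Deterministic master-seed splitting.

A single user-facing seed spawns independent per-stage seeds by hashing
the stage name together with the master seed.  Adding a new stage to the
protocol therefore never perturbs the random draws of existing stages,
and every sub-seed stays below 2**31 so it is portable across RNG APIs.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, stage: str) -> int:
    """Return a stable 31-bit seed for *stage* derived from *master*."""
    digest = hashlib.sha256(f"{stage}|{int(master)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
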
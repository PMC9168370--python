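"""Shared helpers: deterministic sub-seed derivation and logging setup."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("radstab")


def subseed(seed: int, name: str) -> int:
    """Derive a stable sub-seed from a global seed and a stage/stream name.

    Uses SHA-256 so adding a new named stream never shifts existing ones.
    Result is always in [0, 2**31).
    """
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
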
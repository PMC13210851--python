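"""Deterministic seed derivation.

One experiment-level seed fans out to per-stage seeds through a stable hash
of ``"{seed}:{label}"`` so each stage (cohort generation, windowing, each
model's training, bootstrap resampling, ...) is independently reproducible.
Derived seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(seed: int, label: str) -> int:
    digest = hashlib.blake2b(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)
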
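"""Deterministic seed derivation.

Every random stream in the package (simulation, faults, partitioning,
client sampling, mini-batch shuffling, weight init) is seeded with a
sub-seed derived from a master seed plus a stage tag, so stages can be
re-run independently and toggling one stage (e.g. fault injection) never
perturbs another stage's stream.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(*parts: object) -> int:
    """Derive a 31-bit sub-seed from a tuple of hashable tags.

    Stable across platforms and Python processes (uses blake2b, not
    ``hash()``). The result is always in ``[0, 2**31)`` so it is valid
    for any RNG that expects a C ``int`` seed.
    """
    key = "\x1f".join(repr(p) for p in parts).encode("utf-8")
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
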
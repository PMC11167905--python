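"""Deterministic sub-seed derivation.

A single study-level integer seed is fanned out into per-gene / per-stage
sub-seeds with a splitmix64-style finalizer, so that any unit of work
(one gene, one tissue, one replicate) can be re-simulated in isolation
and in any order while remaining byte-reproducible.
"""

from __future__ import annotations

import zlib

_MASK = (1 << 64) - 1


def splitmix64(x: int) -> int:
    """One splitmix64 finalization step (64-bit avalanche hash)."""
    x = (x + 0x9E3779B97F4B07F5) & _MASK
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK
    return (x ^ (x >> 31)) & _MASK


def subseed(seed: int, *tokens: int | str) -> int:
    """Derive a deterministic sub-seed from ``seed`` and mixing tokens.

    String tokens are reduced with CRC32 before mixing; the result is
    kept below 2**63 so it is safe for any RNG constructor.
    """
    state = splitmix64(int(seed) & _MASK)
    for tok in tokens:
        t = zlib.crc32(tok.encode()) if isinstance(tok, str) else int(tok)
        state = splitmix64(state ^ (t & _MASK))
    return state >> 1
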
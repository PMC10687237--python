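"""Shared plumbing: seed derivation and configuration errors."""

from __future__ import annotations

import zlib


class ConfigError(ValueError):
    """Invalid user-supplied configuration or inputs."""


def derive_seed(seed: int, label: str) -> int:
    """Derive a child seed for a named pipeline stage.

    A single global seed fans out to per-stage seeds via a CRC32 of
    ``"{seed}:{label}"``, masked to 31 bits.  Deterministic across
    platforms and Python versions, and stages stay independent: changing
    how one stage consumes randomness never perturbs another.
    """
    return zlib.crc32(f"{seed}:{label}".encode()) & 0x7FFFFFFF
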
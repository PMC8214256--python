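"""Shared helpers: seeded RNG streams and small validation utilities."""

from __future__ import annotations

import numpy as np

# Stable stream keys so that every stage draws from an independent,
# reproducible substream of the master seed.
STREAM_SITES = 1
STREAM_CROSS = 2
STREAM_PHENO = 3
STREAM_READS = 4
STREAM_REFERENCE = 5
STREAM_ALLELES = 6
STREAM_NULLBAND = 7
STREAM_PERMUTATION = 8


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for (master seed, stream key)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream),)))


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)
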
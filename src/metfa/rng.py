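"""Deterministic random-number stream splitting.

Every stochastic routine in the package draws from a stream derived from a
master seed plus a tuple of string/int keys (module name, location, year,
genotype, ...).  Streams are independent, so adding environments or genotypes
to a simulation never perturbs the draws of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "substream_seed"]


def _key_int(key) -> int:
    """Map an arbitrary key to a stable 64-bit integer (platform independent)."""
    data = repr(key).encode("utf-8")
    return int.from_bytes(hashlib.sha256(data).digest()[:8], "little")


def substream_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    """SeedSequence for the (master_seed, *keys) stream."""
    return np.random.SeedSequence([int(master_seed) % (2**63), *(_key_int(k) for k in keys)])


def stream(master_seed: int, *keys) -> np.random.Generator:
    """Generator for the (master_seed, *keys) stream."""
    return np.random.default_rng(substream_seed(master_seed, *keys))
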
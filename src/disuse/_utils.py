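"""Small shared helpers: seeding, validation."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def child_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the global seed.

    Hashes (seed, stage name) with CRC32 so each pipeline stage gets an
    independent, stable stream below 2**31.
    """
    h = zlib.crc32(f"{int(seed)}:{stage}".encode())
    return int(h % MAX_SEED)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))


def as_1d(x, name: str, n: int | None = None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
    return arr
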
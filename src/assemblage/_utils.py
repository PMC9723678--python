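"""Shared plumbing: errors, seeded child RNG streams, provenance hashing."""

from __future__ import annotations

import hashlib
import logging
import zlib

import numpy as np

logger = logging.getLogger("assemblage")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class ConvergenceError(RuntimeError):
    """Raised when MCMC diagnostics indicate the posterior sample is unusable."""


def _key_to_int(key: object) -> int:
    """Stable 32-bit integer for an arbitrary hashable key (strings, ints, floats)."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Derive an independent generator from a global seed and a key path.

    Every stochastic call in the simulator derives its stream from
    (seed, microcosm id, day, purpose), so individual microcosms are
    reproducible independent of iteration order.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def config_hash(obj: object) -> str:
    """Short stable hash of a configuration mapping for provenance headers."""
    canonical = repr(_canonicalise(obj)).encode("utf-8")
    return hashlib.sha256(canonical).hexdigest()[:12]


def _canonicalise(obj: object):
    if isinstance(obj, dict):
        return tuple(sorted((str(k), _canonicalise(v)) for k, v in obj.items()))
    if isinstance(obj, (list, tuple)):
        return tuple(_canonicalise(v) for v in obj)
    if isinstance(obj, float) and float(obj).is_integer():
        return int(obj)
    return obj
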
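"""Seed plumbing: one user seed fans out into named, independent substreams.

Every stochastic component (population init, crossover tie-breaks, VNS
sampling, diversity restarts, synthetic generators) draws from its own
``numpy`` Generator derived from the single run seed, so components are
independently reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "state_digest"]


def _stream_key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def substream(seed: int | None, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Distinct names yield statistically independent streams; the same
    (seed, name) pair always yields the same stream.
    """
    if seed is None:
        return np.random.default_rng()
    ss = np.random.SeedSequence(int(seed), spawn_key=(_stream_key(name),))
    return np.random.default_rng(ss)


def state_digest(rng: np.random.Generator) -> str:
    """Short stable digest of a generator's internal state (for run logs)."""
    state = repr(rng.bit_generator.state).encode("utf-8")
    return hashlib.sha256(state).hexdigest()[:12]
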
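"""Reproducible random-number streams with integer-indexed substreams.

Every source of randomness in the package flows through a :class:`RandomStream`.
Substreams are derived from ``(seed, key...)`` via :class:`numpy.random.SeedSequence`
spawn keys, so they are mutually independent, reproducible across platforms, and
addressable: substream ``(CV, r, ...)`` drives the sample randomization of model
repetition ``r`` (identical across model versions), substream ``(PERM, k)`` draws
permutation ``k`` (identical across repetitions), and so on.
"""

from __future__ import annotations

import numpy as np

# Substream domains.  Fixed small integers so that a given (seed, domain, index)
# always maps to the same generator, independent of call order.
SIM = 0      # cohort geometry and latent variables
RATING = 1   # simulated visual ratings
FLAIR = 2    # synthetic FLAIR intensities
CV = 3       # cross-validation sample randomization (per repetition)
PERM = 4     # WMH-assignment permutations (per permutation index)


class RandomStream:
    """Seeded random stream exposing integer-indexed independent substreams."""

    def __init__(self, seed: int):
        seed = int(seed)
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = seed

    def substream(self, *key: int) -> np.random.Generator:
        """Return a fresh Generator for the given integer key path.

        Calling twice with the same key yields generators in identical states.
        """
        spawn_key = tuple(int(k) for k in key)
        if any(k < 0 for k in spawn_key):
            raise ValueError("substream keys must be non-negative integers")
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=spawn_key))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomStream(seed={self.seed})"
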
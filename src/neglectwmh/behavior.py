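"""Behavioral scoring for spatial neglect: Center of Cancellation and ratings.

The Center of Cancellation (CoC) summarises a paper-and-pencil cancellation
test (letter or bells) as a single continuous score in [-1, +1]: the mean
normalized horizontal position of the cancelled targets, centred by the mean
position of all targets on the sheet.  Complete performance scores 0 on any
sheet; omitting left-sided targets pushes the score positive (left-sided
neglect), omitting right-sided targets pushes it negative.

Also provided: the mean-CoC rule across the two tests (falling back to the
available one when a test is missing), the regression-target preparation
(clamp negatives to 0, then square-root transform), the neglect classification
cutoff, and linearly weighted Cohen's kappa for ordinal rating reliability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Mean-CoC cutoff at or above which a patient is classified as having neglect.
NEGLECT_CUTOFF_MEAN = 0.082
#: Per-test cutoffs for the letter and bells cancellation tasks.
NEGLECT_CUTOFF_LETTER = 0.083
NEGLECT_CUTOFF_BELLS = 0.081


class BehaviorError(ValueError):
    pass


@dataclass
class CancellationSheet:
    """One cancellation test: target positions and hit flags.

    ``x_norm`` holds horizontal target positions scaled to [-1, +1] about the
    sheet centre (negative = left).  ``hit`` marks cancelled targets.
    """

    x_norm: np.ndarray
    hit: np.ndarray

    def __post_init__(self) -> None:
        self.x_norm = np.asarray(self.x_norm, dtype=float)
        self.hit = np.asarray(self.hit, dtype=bool)
        if self.x_norm.ndim != 1 or self.x_norm.shape != self.hit.shape:
            raise BehaviorError("x_norm and hit must be equal-length 1D arrays")
        if self.x_norm.size < 2:
            raise BehaviorError("a cancellation sheet needs at least 2 targets")
        if np.any(np.abs(self.x_norm) > 1):
            raise BehaviorError("target positions must lie in [-1, +1]")

    @property
    def n_hits(self) -> int:
        return int(self.hit.sum())


def center_of_cancellation(
    sheet: CancellationSheet, zero_hit_value: Optional[float] = None
) -> float:
    """Center of Cancellation score in [-1, +1].

    ``mean(x_norm of cancelled targets) - mean(x_norm of all targets)``,
    clipped to [-1, +1].  A sheet with zero cancellations has no defined
    score and raises unless ``zero_hit_value`` supplies an imputation
    (conventionally +1, maximal left neglect, for right-hemisphere cohorts).
    """
    if sheet.n_hits == 0:
        if zero_hit_value is None:
            raise BehaviorError("no cancellations on sheet; CoC undefined (set zero_hit_value to impute)")
        return float(np.clip(zero_hit_value, -1.0, 1.0))
    value = float(sheet.x_norm[sheet.hit].mean() - sheet.x_norm.mean())
    return float(np.clip(value, -1.0, 1.0))


def _present(value: Optional[float]) -> bool:
    return value is not None and not (isinstance(value, float) and math.isnan(value))


def mean_coc(letter: Optional[float], bells: Optional[float]) -> float:
    """Mean CoC over the two cancellation tests; a missing test is skipped."""
    scores = [float(v) for v in (letter, bells) if _present(v)]
    if not scores:
        raise BehaviorError("both cancellation scores missing")
    for s in scores:
        if not -1.0 <= s <= 1.0:
            raise BehaviorError(f"CoC score {s} outside [-1, 1]")
    return float(np.mean(scores))


def prepare_target(mean_coc_value):
    """Regression target: ``sqrt(max(mean CoC, 0))``.

    Negative scores (no right-sided neglect expected in a right-hemisphere
    cohort) are clamped to zero, and the square root reduces the skew of the
    score distribution.  Accepts scalars or arrays; output lies in [0, 1].
    """
    arr = np.asarray(mean_coc_value, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise BehaviorError("mean CoC outside [-1, 1]")
    out = np.sqrt(np.clip(arr, 0.0, None))
    return float(out) if np.isscalar(mean_coc_value) or arr.ndim == 0 else out


def classify_neglect(mean_coc_value: float, cutoff: float = NEGLECT_CUTOFF_MEAN) -> bool:
    """True iff the mean CoC reaches the neglect cutoff (inclusive)."""
    return bool(float(mean_coc_value) >= cutoff)


def weighted_kappa(
    ratings_a: Sequence[int], ratings_b: Sequence[int], n_levels: int
) -> tuple[float, float]:
    """Linearly weighted Cohen's kappa and weighted relative agreement (%).

    Disagreement weights are ``w_ij = |i - j| / (n_levels - 1)``;
    ``kappa = 1 - sum(w * O) / sum(w * E)`` with observed proportions O and
    chance-expected proportions E from the marginals.  The second return value
    is the weighted relative agreement ``100 * (1 - sum(w * O))``.
    """
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise BehaviorError("ratings must be equal-length non-empty 1D vectors")
    if n_levels < 2:
        raise BehaviorError("n_levels must be >= 2")
    if a.min() < 0 or b.min() < 0 or a.max() >= n_levels or b.max() >= n_levels:
        raise BehaviorError(f"ratings must lie in [0, {n_levels - 1}]")
    n = a.size
    observed = np.zeros((n_levels, n_levels))
    np.add.at(observed, (a, b), 1.0)
    observed /= n
    idx = np.arange(n_levels)
    weights = np.abs(idx[:, None] - idx[None, :]) / (n_levels - 1)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    wo = float((weights * observed).sum())
    we = float((weights * expected).sum())
    agreement_pct = 100.0 * (1.0 - wo)
    if we == 0.0:
        # both raters constant: perfect agreement iff identical (wo == 0)
        return (1.0 if wo == 0.0 else 0.0), agreement_pct
    return 1.0 - wo / we, agreement_pct
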
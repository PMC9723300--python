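"""PCA reduction of voxel blocks with cumulative-variance retention.

Voxel blocks are centred (not variance-scaled — the columns are binary damage
indicators on a common scale) and decomposed by SVD; the smallest number of
leading components whose explained-variance ratios sum to at least the
threshold (default 94 %) is retained, and each retained component score is
min-max normalized to [0, 1] like the scalar features.  Scalar columns never
enter the PCA.

Sign convention: the largest-magnitude loading element of every component is
made positive (ties resolved by first index), for determinism across BLAS
implementations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .features import ColumnMeta, FeatureMatrix


class ReductionError(ValueError):
    pass


@dataclass
class PcaModel:
    mean: np.ndarray                      # (p,) column means
    components: np.ndarray                # (k, p) retained loadings
    explained_variance_ratio: np.ndarray  # full spectrum, non-increasing
    k_retained: int
    score_min: np.ndarray                 # (k,) per-component min on fit data
    score_max: np.ndarray                 # (k,) per-component max on fit data
    var_threshold: float

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "k_retained": int(self.k_retained),
            "score_min": self.score_min.tolist(),
            "score_max": self.score_max.tolist(),
            "var_threshold": float(self.var_threshold),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PcaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
            k_retained=int(d["k_retained"]),
            score_min=np.asarray(d["score_min"], dtype=float),
            score_max=np.asarray(d["score_max"], dtype=float),
            var_threshold=float(d["var_threshold"]),
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def pca_fit(block: Union[FeatureMatrix, np.ndarray], var_threshold: float = 0.94) -> PcaModel:
    """Fit a PCA on a voxel block and pick the minimal k reaching the
    cumulative explained-variance threshold."""
    X = block.values if isinstance(block, FeatureMatrix) else np.asarray(block, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ReductionError("PCA needs a 2D block with at least 2 rows")
    if not 0 < var_threshold <= 1:
        raise ReductionError("var_threshold must lie in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc**2).sum())
    if total_var == 0.0:
        raise ReductionError("all-constant block: no variance to decompose")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    ratios = var / var.sum()
    cumulative = np.cumsum(ratios)
    # minimal k with cumulative ratio >= threshold (guard float round-off)
    k = int(np.searchsorted(cumulative, var_threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    components = _fix_signs(vt[:k])
    scores = Xc @ components.T
    return PcaModel(
        mean=mean,
        components=components,
        explained_variance_ratio=ratios,
        k_retained=k,
        score_min=scores.min(axis=0),
        score_max=scores.max(axis=0),
        var_threshold=float(var_threshold),
    )


def pca_scores_self(X: np.ndarray, var_threshold: float = 0.94) -> np.ndarray:
    """Min-max-normalized retained-component scores of ``X`` on itself.

    Mathematically equivalent to ``pca_transform(pca_fit(X, t), X)`` up to
    per-column orientation flips (x -> 1 - x), which leave all pairwise
    distances — and hence any RBF-kernel model — unchanged.  Computed via the
    n x n Gram matrix of the centred data, so the cost is independent of the
    voxel count; used on the permutation-test hot path.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ReductionError("PCA needs a 2D block with at least 2 rows")
    if not 0 < var_threshold <= 1:
        raise ReductionError("var_threshold must lie in (0, 1]")
    Xc = X - X.mean(axis=0)
    gram = Xc @ Xc.T
    evals, evecs = np.linalg.eigh(gram)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total == 0.0:
        raise ReductionError("all-constant block: no variance to decompose")
    ratios = evals / total
    k = int(np.searchsorted(np.cumsum(ratios), var_threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    lo = scores.min(axis=0)
    span = scores.max(axis=0) - lo
    if np.any(span <= 0):
        raise ReductionError("degenerate component: zero score range")
    return (scores - lo) / span


def pca_transform(
    model: PcaModel, block: Union[FeatureMatrix, np.ndarray], block_name: str = "pca"
) -> FeatureMatrix:
    """Project onto the retained components and min-max normalize each score
    column with the ranges stored at fit time."""
    X = block.values if isinstance(block, FeatureMatrix) else np.asarray(block, dtype=float)
    if X.shape[1] != model.mean.shape[0]:
        raise ReductionError(
            f"block has {X.shape[1]} columns, model expects {model.mean.shape[0]}"
        )
    scores = (X - model.mean) @ model.components.T
    span = model.score_max - model.score_min
    if np.any(span <= 0):
        raise ReductionError("degenerate component: zero score range")
    normalized = (scores - model.score_min) / span
    meta = [ColumnMeta("component", i, block_name) for i in range(model.k_retained)]
    return FeatureMatrix(normalized, meta)
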
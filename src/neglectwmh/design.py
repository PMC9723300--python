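"""Build the final design matrix for a model version: PCA-reduced voxel
blocks (fitted separately per block, then concatenated) plus normalized
scalar columns.

By default the PCA is fitted once on the full cohort before
cross-validation (pooled mode).  A fold-safe mode (PCA fitted inside each
outer training set only) is available through :func:`make_fold_safe_builder`.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .features import (
    AssembledFeatures,
    FeatureMatrix,
    ModelVersionSpec,
    assemble_features,
    fuse_concatenate,
)
from .reduction import pca_fit, pca_transform
from .simulate import CohortTable

DEFAULT_VAR_THRESHOLD = 0.94


def reduce_assembled(
    assembled: AssembledFeatures, var_threshold: float = DEFAULT_VAR_THRESHOLD
) -> FeatureMatrix:
    """PCA-reduce each voxel block and append the scalar columns."""
    reduced: list[FeatureMatrix] = []
    for name, block in assembled.voxel_blocks:
        model = pca_fit(block, var_threshold)
        reduced.append(pca_transform(model, block, block_name=name))
    out = reduced[0]
    extras: list = list(reduced[1:]) + [(name, vec) for name, vec in assembled.scalars]
    if extras:
        out = fuse_concatenate(out, extras)
    return out


def build_design(
    cohort: CohortTable,
    spec: Union[ModelVersionSpec, str],
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    perm: Optional[np.ndarray] = None,
) -> FeatureMatrix:
    """Assemble and reduce the feature matrix for one model version."""
    return reduce_assembled(assemble_features(cohort, spec, perm=perm), var_threshold)


def make_fold_safe_builder(
    cohort: CohortTable,
    spec: Union[ModelVersionSpec, str],
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    perm: Optional[np.ndarray] = None,
):
    """Return ``builder(train_idx, test_idx) -> (X_train, X_test)`` that fits
    the PCA on the outer-fold training rows only."""
    assembled = assemble_features(cohort, spec, perm=perm)

    def builder(train_idx: np.ndarray, test_idx: np.ndarray):
        train_parts, test_parts = [], []
        for name, block in assembled.voxel_blocks:
            model = pca_fit(block.values[train_idx], var_threshold)
            train_parts.append(pca_transform(model, block.values[train_idx], name).values)
            test_parts.append(pca_transform(model, block.values[test_idx], name).values)
        for _, vec in assembled.scalars:
            train_parts.append(vec[train_idx, None])
            test_parts.append(vec[test_idx, None])
        return np.hstack(train_parts), np.hstack(test_parts)

    return builder
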
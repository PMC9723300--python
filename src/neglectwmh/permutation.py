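"""Permutation test for the contribution of correctly paired WMH data.

The null hypothesis is that the patient-specific lesion-WMH pairing carries no
information about neglect severity beyond the lesion alone.  Each permutation
re-pairs every patient's lesion with another patient's WMH data (maps and
ratings alike; lesions and targets stay put), rebuilds the feature matrix —
for added matrices, overlaps between a lesion and a foreign WMH map are reset
to one to keep the matrix binary — and reruns the repetition-averaged
prediction pipeline.  Permutation k uses substream k, so the same pairing is
applied across all repetitions and across model versions.

The one-tailed Monte-Carlo p-value uses the add-one counting rule
``p = (1 + #{null R^2 >= true R^2}) / (n_perm + 1)``; the 95th-percentile
decision rule (true R² beats the 95 %-best null R²) is reported alongside.

Modes
-----
``full``
    The full pipeline — PCA refit and per-fold hyperparameter grid search —
    is rerun for every permutation.
``fast`` (approximate, desk-scale default)
    The PCA is refit on the permuted features, but the per-fold (C, gamma)
    chosen on the true pairing are reused, so each permutation costs only one
    SVR fit per outer fold and repetition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .design import DEFAULT_VAR_THRESHOLD, build_design
from .features import (
    LESION_MIN_COUNT,
    WMH_MIN_COUNT,
    FeatureError,
    ModelVersionSpec,
    MODEL_VERSIONS,
    minmax_normalize,
)
from .reduction import pca_scores_self
from .simulate import CohortTable
from .streams import PERM, RandomStream
from .svr import CvConfig, FitResult, fit_svr, r_squared, run_repetitions


@dataclass
class NullDistribution:
    null_r2: np.ndarray
    true_r2: float
    p_value: float
    n_perm: int
    #: decision by the quantile rule: true R² exceeds the 95 %-best null R²
    significant_quantile_rule: bool

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"null_r2": self.null_r2}).to_csv(path, index=False)
        return path

    def plot(self, path: str | Path):
        """Histogram of the null distribution with the true R² marked."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(self.null_r2, bins=40, color="0.7", edgecolor="0.4")
        ax.axvline(self.true_r2, color="crimson", linestyle="--", label=f"true R²={self.true_r2:.3f}")
        ax.set_xlabel("null R²")
        ax.set_ylabel("count")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)


def permute_wmh_assignment(n: int, stream: RandomStream, k: int) -> np.ndarray:
    """Uniform random pairing permutation for permutation index ``k`` —
    identical across repetitions and model versions for a given seed."""
    return stream.substream(PERM, int(k)).permutation(n)


def permutation_pvalue(null_r2: np.ndarray, true_r2: float) -> float:
    """One-tailed (greater) add-one Monte-Carlo p-value."""
    null_r2 = np.asarray(null_r2, dtype=float)
    if null_r2.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + int((null_r2 >= true_r2).sum())) / (null_r2.size + 1))


def _perm_design_builder(cohort: CohortTable, spec: ModelVersionSpec, var_threshold: float):
    """Return ``f(pi) -> X`` producing the permuted-pairing design matrix.

    Exploits two permutation invariances for speed: across-patient voxel
    damage counts (hence all retention masks) are unchanged by re-pairing, and
    min-max normalization commutes with row permutation.  Voxel blocks are
    reduced with :func:`pca_scores_self` (distance-equivalent to the regular
    fit/transform path), so the per-permutation cost is independent of the
    voxel count.
    """
    t = cohort.table
    age = (
        minmax_normalize(t["age"].to_numpy(dtype=float))[:, None]
        if spec.include_age
        else None
    )
    if spec.fusion == "add_map":
        L = cohort.lesion_matrix()
        W = cohort.wmh_matrix(side=spec.map_side)
        mask = ((L > 0).sum(axis=0) >= LESION_MIN_COUNT) | (
            (W > 0).sum(axis=0) >= WMH_MIN_COUNT
        )
        Lm = (L[:, mask] > 0).astype(float)
        Wm = (W[:, mask] > 0).astype(float)

        def build(pi: np.ndarray) -> np.ndarray:
            raw = np.clip(Lm + Wm[pi], 0.0, 1.0)  # binarized: overlaps become 1
            X = pca_scores_self(raw, var_threshold)
            return X if age is None else np.hstack([X, age])

        return build

    lesion_scores = pca_scores_self(
        (cohort.lesion_matrix() > 0).astype(float)[
            :, (cohort.lesion_matrix() > 0).sum(axis=0) >= LESION_MIN_COUNT
        ],
        var_threshold,
    )
    if spec.fusion == "concat_map":
        W = cohort.wmh_matrix(side=spec.map_side)
        wmask = (W > 0).sum(axis=0) >= WMH_MIN_COUNT
        Wm = (W[:, wmask] > 0).astype(float)

        def build(pi: np.ndarray) -> np.ndarray:
            parts = [lesion_scores, pca_scores_self(Wm[pi], var_threshold)]
            if age is not None:
                parts.append(age)
            return np.hstack(parts)

        return build

    # concat_scalar: normalized scalar columns, re-paired by the permutation
    cols = []
    source_cols = {
        "chs": ["chs"],
        "pv": ["pv_wmh"],
        "ds": ["ds_wmh"],
        "pv_and_ds": ["pv_wmh", "ds_wmh"],
        "volume": ["wmh_volume_cm3"],
    }[spec.wmh_source]
    for col in source_cols:
        cols.append(minmax_normalize(t[col].to_numpy(dtype=float)))
    scal = np.column_stack(cols)

    def build(pi: np.ndarray) -> np.ndarray:
        parts = [lesion_scores, scal[pi]]
        if age is not None:
            parts.append(age)
        return np.hstack(parts)

    return build


def null_distribution(
    cohort: CohortTable,
    spec: Union[ModelVersionSpec, str],
    config: CvConfig,
    n_perm: int,
    stream: RandomStream,
    mode: str = "fast",
    var_threshold: float = DEFAULT_VAR_THRESHOLD,
    true_fit: Optional[FitResult] = None,
) -> NullDistribution:
    """Build the permutation null for a WMH-bearing model version.

    ``true_fit`` may pass in the already-computed fit of the true pairing
    (same config and stream) to avoid refitting it.
    """
    if isinstance(spec, str):
        spec = MODEL_VERSIONS[spec]
    if not spec.uses_wmh:
        raise FeatureError(f"model version {spec.name!r} carries no WMH information to permute")
    if mode not in ("fast", "full"):
        raise ValueError("mode must be 'fast' or 'full'")
    y = cohort.targets()
    n = cohort.n
    if true_fit is None:
        X_true = build_design(cohort, spec, var_threshold).values
        true_fit = run_repetitions(X_true, y, config, stream)
    true_r2 = true_fit.r2_averaged

    fast_builder = _perm_design_builder(cohort, spec, var_threshold) if mode == "fast" else None
    null_r2 = np.empty(n_perm)
    for k in range(n_perm):
        pi = permute_wmh_assignment(n, stream, k)
        if mode == "full":
            Xk = build_design(cohort, spec, var_threshold, perm=pi).values
            fit_k = run_repetitions(Xk, y, config, stream)
            avg_pred = fit_k.averaged_predictions
        else:
            Xk = fast_builder(pi)
            preds = np.empty((config.n_repetitions, n))
            for r in range(config.n_repetitions):
                folds = true_fit.fold_assignments[r]
                for j in range(config.outer_k):
                    train = folds != j
                    test = folds == j
                    C, gamma = true_fit.chosen_params[r][j]
                    model = fit_svr(Xk[train], y[train], C, gamma, config.epsilon)
                    preds[r, test] = model.predict(Xk[test])
            avg_pred = preds.mean(axis=0)
        null_r2[k] = r_squared(avg_pred, y)

    p = permutation_pvalue(null_r2, true_r2)
    quantile_rule = bool(true_r2 > np.quantile(null_r2, 0.95))
    return NullDistribution(
        null_r2=null_r2,
        true_r2=float(true_r2),
        p_value=p,
        n_perm=int(n_perm),
        significant_quantile_rule=quantile_rule,
    )
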
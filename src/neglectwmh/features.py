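"""Feature-matrix construction and the two lesion/WMH fusion schemes.

Model versions differ only in how WMH information enters the feature matrix
next to the voxel-based lesion map (rows = patients, columns = features):

* ``concat_scalar`` — append min-max-normalized scalar column(s): a visual
  rating (CHS, Fazekas PV, DS, or PV and DS), the WMH volume, or age;
* ``concat_map`` — append the voxel-based WMH map as a second voxel block
  (reduced separately before concatenation);
* ``add_map`` — voxel-wise addition of lesion and WMH maps on the union of
  their retained-voxel masks, treating WMH as part of the brain lesion.

Voxel retention filters: lesion voxels damaged in at least 5 patients, WMH
voxels damaged at least once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import json
import numpy as np
import pandas as pd

from .simulate import CohortTable
from .volumes import Volume

LESION_MIN_COUNT = 5
WMH_MIN_COUNT = 1


class FeatureError(ValueError):
    pass


@dataclass
class ColumnMeta:
    """Provenance of one feature column."""

    kind: str          # "voxel" | "component" | "scalar"
    ref: Union[int, str]  # voxel linear index, component index, or scalar name
    block: str         # source block, e.g. "lesion", "wmh", "added"


@dataclass
class FeatureMatrix:
    """Patients × features matrix with per-column provenance."""

    values: np.ndarray
    column_meta: list[ColumnMeta]
    voxel_mask: Optional[np.ndarray] = None  # linear voxel indices of retained columns

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FeatureError("feature matrix must be 2D (patients x features)")
        if len(self.column_meta) != self.values.shape[1]:
            raise FeatureError("column_meta length mismatch")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> Path:
        """Export values as TSV with a sidecar JSON provenance file."""
        path = Path(path)
        pd.DataFrame(self.values).to_csv(path, sep="\t", index=False, header=False)
        meta = [
            {"kind": m.kind, "ref": int(m.ref) if isinstance(m.ref, (int, np.integer)) else m.ref,
             "block": m.block}
            for m in self.column_meta
        ]
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
        return path


VALID_FUSIONS = {"none", "concat_scalar", "concat_map", "add_map"}
VALID_WMH_SOURCES = {
    "none", "chs", "pv", "ds", "pv_and_ds", "volume",
    "map_bilateral", "map_left", "map_right",
}
_MAP_SOURCES = {"map_bilateral", "map_left", "map_right"}


@dataclass(frozen=True)
class ModelVersionSpec:
    """One model version: which WMH information is fused, and how."""

    name: str
    fusion: str = "none"
    wmh_source: str = "none"
    include_age: bool = False

    def __post_init__(self) -> None:
        if self.fusion not in VALID_FUSIONS:
            raise FeatureError(f"unknown fusion {self.fusion!r}")
        if self.wmh_source not in VALID_WMH_SOURCES:
            raise FeatureError(f"unknown wmh_source {self.wmh_source!r}")
        if self.fusion == "add_map" and self.wmh_source not in _MAP_SOURCES:
            raise FeatureError("add_map fusion requires a map wmh_source")
        if self.fusion == "none" and self.wmh_source != "none":
            raise FeatureError("fusion 'none' is incompatible with a WMH source")
        if self.fusion == "concat_scalar" and self.wmh_source in _MAP_SOURCES:
            raise FeatureError("concat_scalar needs a scalar wmh_source")
        if self.fusion == "concat_map" and self.wmh_source not in _MAP_SOURCES:
            raise FeatureError("concat_map needs a map wmh_source")

    @property
    def uses_wmh(self) -> bool:
        return self.wmh_source != "none"

    @property
    def map_side(self) -> str:
        return {"map_bilateral": "bilateral", "map_left": "left", "map_right": "right"}[
            self.wmh_source
        ]


#: The twelve model versions the pipeline compares.
MODEL_VERSIONS: dict[str, ModelVersionSpec] = {
    s.name: s
    for s in [
        ModelVersionSpec("base"),
        ModelVersionSpec("chs", "concat_scalar", "chs"),
        ModelVersionSpec("pv", "concat_scalar", "pv"),
        ModelVersionSpec("ds", "concat_scalar", "ds"),
        ModelVersionSpec("pv_ds", "concat_scalar", "pv_and_ds"),
        ModelVersionSpec("wmh_volume", "concat_scalar", "volume"),
        ModelVersionSpec("concat_map", "concat_map", "map_bilateral"),
        ModelVersionSpec("add_bilateral", "add_map", "map_bilateral"),
        ModelVersionSpec("add_left", "add_map", "map_left"),
        ModelVersionSpec("add_right", "add_map", "map_right"),
        ModelVersionSpec("age", "none", "none", include_age=True),
        ModelVersionSpec("add_bilateral_age", "add_map", "map_bilateral", include_age=True),
    ]
}


def _as_map_matrix(maps: Union[np.ndarray, Sequence[Volume]]) -> np.ndarray:
    """Stack a list of binary Volumes (or pass through an array) to (n, n_voxels)."""
    if isinstance(maps, np.ndarray):
        if maps.ndim == 2:
            return maps
        if maps.ndim == 4:
            return maps.reshape(maps.shape[0], -1)
        raise FeatureError("map array must be (n, n_voxels) or (n, nx, ny, nz)")
    vols = list(maps)
    if not vols:
        raise FeatureError("empty map list")
    first = vols[0]
    for v in vols[1:]:
        first.check_same_grid(v)
    for v in vols:
        v.require_binary("map")
    return np.stack([v.data.reshape(-1) for v in vols])


def build_voxel_matrix(
    maps: Union[np.ndarray, Sequence[Volume]], min_count: int, block: str = "voxel"
) -> FeatureMatrix:
    """Dichotomized voxel-status matrix over voxels damaged in >= ``min_count``
    patients."""
    if min_count < 1:
        raise FeatureError("min_count must be >= 1")
    mat = _as_map_matrix(maps)
    counts = (mat > 0).sum(axis=0)
    mask = np.flatnonzero(counts >= min_count)
    values = (mat[:, mask] > 0).astype(float)
    meta = [ColumnMeta("voxel", int(i), block) for i in mask]
    return FeatureMatrix(values, meta, voxel_mask=mask)


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Rescale to [0, 1]: (x - min) / (max - min); constant input is degenerate."""
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise FeatureError("cannot min-max normalize a constant vector")
    return (x - lo) / (hi - lo)


def fuse_concatenate(
    base: FeatureMatrix,
    extras: Sequence[Union[FeatureMatrix, tuple[str, np.ndarray]]],
) -> FeatureMatrix:
    """Append scalar columns and/or further feature blocks to ``base``."""
    blocks = [base.values]
    meta = list(base.column_meta)
    for extra in extras:
        if isinstance(extra, FeatureMatrix):
            if extra.n_patients != base.n_patients:
                raise FeatureError("row count mismatch in concatenation")
            blocks.append(extra.values)
            meta.extend(extra.column_meta)
        else:
            name, vec = extra
            vec = np.asarray(vec, dtype=float).reshape(-1, 1)
            if vec.shape[0] != base.n_patients:
                raise FeatureError("row count mismatch in concatenation")
            blocks.append(vec)
            meta.append(ColumnMeta("scalar", name, "scalar"))
    return FeatureMatrix(np.hstack(blocks), meta, voxel_mask=base.voxel_mask)


def fuse_add(
    lesions: Union[np.ndarray, Sequence[Volume]],
    wmhs: Union[np.ndarray, Sequence[Volume]],
    lesion_min: int = LESION_MIN_COUNT,
    wmh_min: int = WMH_MIN_COUNT,
    binarize: bool = False,
) -> FeatureMatrix:
    """Voxel-wise addition of lesion and WMH maps.

    The voxel mask is the union of voxels lesioned in at least ``lesion_min``
    patients and voxels hyperintense in at least ``wmh_min`` patients; per
    patient the row is lesion + WMH restricted to that mask.  With lesion-
    masked WMH the maps are disjoint and the sum is already binary; when a
    shuffled WMH assignment can overlap the lesion, ``binarize`` resets all
    non-zeros to one to keep the matrix binary.
    """
    L = _as_map_matrix(lesions)
    W = _as_map_matrix(wmhs)
    if L.shape != W.shape:
        raise FeatureError(f"lesion/WMH list mismatch: {L.shape} vs {W.shape}")
    mask = np.flatnonzero(
        ((L > 0).sum(axis=0) >= lesion_min) | ((W > 0).sum(axis=0) >= wmh_min)
    )
    values = (L[:, mask] > 0).astype(float) + (W[:, mask] > 0).astype(float)
    if binarize:
        values = (values > 0).astype(float)
    meta = [ColumnMeta("voxel", int(i), "added") for i in mask]
    return FeatureMatrix(values, meta, voxel_mask=mask)


@dataclass
class AssembledFeatures:
    """Pre-reduction voxel blocks plus already-normalized scalar columns."""

    voxel_blocks: list[tuple[str, FeatureMatrix]]
    scalars: list[tuple[str, np.ndarray]]
    spec: ModelVersionSpec


def assemble_features(
    cohort: CohortTable,
    spec: Union[ModelVersionSpec, str],
    perm: Optional[np.ndarray] = None,
) -> AssembledFeatures:
    """Assemble the raw feature blocks for one model version.

    ``perm`` re-pairs each patient's lesion with another patient's WMH data
    (maps, ratings and WMH volume alike) for permutation testing; in that case
    added matrices are binarized because overlaps can occur.  Age is a patient
    attribute and is never permuted.
    """
    if isinstance(spec, str):
        try:
            spec = MODEL_VERSIONS[spec]
        except KeyError:
            raise FeatureError(f"unknown model version {spec!r}") from None
    t = cohort.table
    perm_idx = None if perm is None else np.asarray(perm, dtype=int)

    def scalar(col: str) -> np.ndarray:
        vals = t[col].to_numpy(dtype=float)
        if perm_idx is not None:
            vals = vals[perm_idx]
        return minmax_normalize(vals)

    blocks: list[tuple[str, FeatureMatrix]] = []
    scalars: list[tuple[str, np.ndarray]] = []
    L = cohort.lesion_matrix()

    if spec.fusion == "add_map":
        W = cohort.wmh_matrix(side=spec.map_side, perm=perm_idx)
        blocks.append(
            ("added", fuse_add(L, W, binarize=perm_idx is not None))
        )
    else:
        blocks.append(("lesion", build_voxel_matrix(L, LESION_MIN_COUNT, block="lesion")))
        if spec.fusion == "concat_map":
            W = cohort.wmh_matrix(side=spec.map_side, perm=perm_idx)
            blocks.append(("wmh", build_voxel_matrix(W, WMH_MIN_COUNT, block="wmh")))
        elif spec.fusion == "concat_scalar":
            if spec.wmh_source == "chs":
                scalars.append(("chs", scalar("chs")))
            elif spec.wmh_source == "pv":
                scalars.append(("pv", scalar("pv_wmh")))
            elif spec.wmh_source == "ds":
                scalars.append(("ds", scalar("ds_wmh")))
            elif spec.wmh_source == "pv_and_ds":
                scalars.append(("pv", scalar("pv_wmh")))
                scalars.append(("ds", scalar("ds_wmh")))
            elif spec.wmh_source == "volume":
                scalars.append(("wmh_volume", scalar("wmh_volume_cm3")))

    if spec.include_age:
        scalars.append(("age", minmax_normalize(t["age"].to_numpy(dtype=float))))

    return AssembledFeatures(blocks, scalars, spec)
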
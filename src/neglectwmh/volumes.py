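"""Voxel-space brain maps: NIfTI I/O, cluster segmentation, map arithmetic.

All maps live on a common voxel grid (no resampling is performed; the affine is
carried through I/O but otherwise ignored).  Binary maps encode damage status per
voxel; real-valued volumes hold image intensities.  The voxel x-index increases
left-to-right, so the right hemisphere occupies the upper half of the x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Raised for invalid volumes, grid mismatches, and unreadable files."""


# scipy.ndimage structure rank for the three standard 3D neighbourhoods
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class Volume:
    """A 3D voxel volume with grid metadata.

    Parameters
    ----------
    data:
        3D array; {0, 1} for binary maps, arbitrary reals for intensities.
    voxel_size_mm:
        Positive voxel edge lengths per axis, in millimetres.
    affine:
        Optional voxel-to-world affine (stored, never used for resampling).
    x_left_to_right:
        Convention flag: voxel x-index increases from the patient's left to
        their right.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None
    x_left_to_right: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"Volume data must be 3D, got {self.data.ndim}D")
        if any(s <= 0 for s in self.data.shape):
            raise VolumeError(f"Volume shape must be positive, got {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise VolumeError(f"voxel_size_mm must be 3 positive reals, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def require_binary(self, what: str = "Volume") -> None:
        if not self.is_binary():
            raise VolumeError(f"{what} must be binary (values in {{0, 1}})")

    def check_same_grid(self, other: "Volume") -> None:
        if self.shape != other.shape:
            raise VolumeError(f"grid mismatch: shapes {self.shape} vs {other.shape}")
        if self.voxel_size_mm != other.voxel_size_mm:
            raise VolumeError(
                f"grid mismatch: voxel sizes {self.voxel_size_mm} vs {other.voxel_size_mm}"
            )

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class SegmentationParams:
    """Threshold segmentation parameters.

    ``min_cluster_voxels`` defaults to 100, the conventional minimum for stroke
    lesion delineation; small punctate hyperintensities call for 10.
    """

    threshold: float
    min_cluster_voxels: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        self.min_cluster_voxels = int(self.min_cluster_voxels)
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 image (.nii / .nii.gz) into a :class:`Volume`."""
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
        affine = np.asarray(img.affine)
    except VolumeError:
        raise
    except Exception as exc:  # unreadable / corrupt header
        raise VolumeError(f"cannot read NIfTI image {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeError(f"{path} is {data.ndim}D; only 3D images are supported")
    return Volume(
        data=np.asarray(data, dtype=np.float64),
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        affine=affine,
    )


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a :class:`Volume` as NIfTI-1; binary maps are stored as uint8."""
    path = Path(path)
    if vol.affine is not None:
        affine = vol.affine
    else:
        affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    data = vol.data
    dtype = np.uint8 if vol.is_binary() else np.float64
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeError(f"cannot write NIfTI image {path}: {exc}") from exc
    return path


def clusterize_segment(
    intensity: Volume,
    params: SegmentationParams,
    exclusion_mask: Optional[Volume] = None,
    include_labels: Optional[list[int]] = None,
) -> Volume:
    """Threshold an intensity volume and keep connected clusters above a size floor.

    Marks every voxel belonging to a connected component of
    ``{intensity >= threshold}`` whose voxel count is at least
    ``params.min_cluster_voxels``; everything else is 0.  The original
    semi-automated workflow had a human select lesion clusters per slice; here
    all passing clusters are kept automatically, with an optional
    ``include_labels`` whitelist of component labels for curated selections and
    an optional ``exclusion_mask`` (e.g. ventricles) removed before labelling.
    """
    if intensity.data.size == 0:
        raise VolumeError("cannot segment an empty volume")
    mask = intensity.data >= params.threshold
    if exclusion_mask is not None:
        intensity.check_same_grid(exclusion_mask)
        exclusion_mask.require_binary("exclusion mask")
        mask &= exclusion_mask.data == 0
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[params.connectivity])
    labels, n_labels = ndimage.label(mask, structure=structure)
    if n_labels == 0:
        return intensity.with_data(np.zeros(intensity.shape, dtype=np.uint8))
    sizes = np.bincount(labels.ravel())
    keep = sizes >= params.min_cluster_voxels
    keep[0] = False
    if include_labels is not None:
        allowed = np.zeros_like(keep)
        for lab in include_labels:
            if 0 < lab < len(allowed):
                allowed[lab] = True
        keep &= allowed
    out = keep[labels].astype(np.uint8)
    return intensity.with_data(out)


def mask_wmh_by_lesion(wmh: Volume, lesion: Volume) -> Volume:
    """Remove lesion voxels from a WMH map: ``wmh AND NOT lesion``.

    Keeps the stroke lesion and the chronic hyperintensity map disjoint where
    the WMH delineation abuts the acute lesion.
    """
    wmh.check_same_grid(lesion)
    wmh.require_binary("wmh map")
    lesion.require_binary("lesion map")
    out = (wmh.data.astype(bool) & ~lesion.data.astype(bool)).astype(np.uint8)
    return wmh.with_data(out)


def split_hemispheres(vol: Volume, midplane: Optional[int] = None) -> tuple[Volume, Volume]:
    """Split a map at the midsagittal plane into (left, right) hemisphere maps.

    With x increasing left-to-right, the left map keeps voxels with
    ``x < midplane`` and the right map the rest.  For even nx the midplane
    defaults to nx/2; odd nx requires an explicit midplane index.
    """
    nx = vol.shape[0]
    if midplane is None:
        if nx % 2 != 0:
            raise VolumeError(f"nx={nx} is odd; supply an explicit midplane index")
        midplane = nx // 2
    if not 0 < midplane < nx:
        raise VolumeError(f"midplane {midplane} outside (0, {nx})")
    left_data = vol.data.copy()
    left_data[midplane:, :, :] = 0
    right_data = vol.data.copy()
    right_data[:midplane, :, :] = 0
    return vol.with_data(left_data), vol.with_data(right_data)


def volume_cm3(vol: Volume) -> float:
    """Volume of a binary map in cm³ (voxel count × voxel volume / 1000)."""
    vol.require_binary()
    return float(vol.data.sum()) * vol.voxel_volume_mm3 / 1000.0
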
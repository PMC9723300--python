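"""Map I/O round-trips, cluster segmentation vs a flood-fill oracle, and map
arithmetic (lesion masking, hemisphere split, volume quantification)."""

import numpy as np
import pytest

from neglectwmh import (
    SegmentationParams,
    Volume,
    clusterize_segment,
    mask_wmh_by_lesion,
    read_volume,
    split_hemispheres,
    volume_cm3,
    write_volume,
)
from neglectwmh.volumes import VolumeError

# ---------------------------------------------------------------------------
# independent flood-fill oracle for connected components

_NEIGHBORS = {
    6: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) == 1],
    18: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if 0 < abs(dx) + abs(dy) + abs(dz) <= 2],
    26: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)],
}


def flood_fill_segment(data, threshold, min_size, connectivity):
    """Brute-force BFS reference for threshold-plus-cluster-size segmentation."""
    mask = data >= threshold
    visited = np.zeros_like(mask, dtype=bool)
    out = np.zeros_like(mask, dtype=np.uint8)
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        component = []
        while stack:
            vox = stack.pop()
            component.append(vox)
            for d in _NEIGHBORS[connectivity]:
                nb = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
                if all(0 <= nb[i] < shape[i] for i in range(3)) and mask[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        if len(component) >= min_size:
            for vox in component:
                out[vox] = 1
    return out


class TestIO:
    def test_binary_roundtrip_bit_exact(self, tmp_path, rng):
        data = (rng.random((8, 10, 6)) > 0.6).astype(np.uint8)
        vol = Volume(data, voxel_size_mm=(2.0, 2.0, 2.0))
        path = write_volume(vol, tmp_path / "map.nii.gz")
        back = read_volume(path)
        assert np.array_equal(back.data, data)
        assert back.voxel_size_mm == (2.0, 2.0, 2.0)
        assert set(np.unique(back.data)) <= {0, 1}

    def test_real_volume_roundtrip(self, tmp_path, rng):
        data = rng.normal(100, 5, size=(6, 6, 6))
        path = write_volume(Volume(data), tmp_path / "flair.nii")
        assert np.allclose(read_volume(path).data, data)

    def test_overwrite_replaces_content(self, tmp_path):
        path = tmp_path / "map.nii.gz"
        write_volume(Volume(np.zeros((4, 4, 4))), path)
        write_volume(Volume(np.ones((4, 4, 4))), path)
        assert read_volume(path).data.sum() == 64

    def test_missing_file_and_4d_rejected(self, tmp_path):
        with pytest.raises(VolumeError):
            read_volume(tmp_path / "nope.nii.gz")
        import nibabel as nib
        p = tmp_path / "fourd.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 3)), np.eye(4)), str(p))
        with pytest.raises(VolumeError):
            read_volume(p)

    def test_header_voxel_size_passthrough(self, tmp_path):
        path = write_volume(Volume(np.zeros((5, 5, 5)), voxel_size_mm=(1, 1, 1)), tmp_path / "v.nii")
        assert read_volume(path).voxel_size_mm == (1.0, 1.0, 1.0)


class TestClusterize:
    def test_large_blob_kept_small_blob_dropped(self):
        data = np.zeros((20, 20, 20))
        data[2:8, 2:7, 2:7] = 200.0          # 6*5*5 = 150 voxels
        data[12:17, 12:14, 12:17] = 200.0    # 5*2*5 = 50 voxels
        params = SegmentationParams(threshold=130, min_cluster_voxels=100)
        out = clusterize_segment(Volume(data), params)
        expected = np.zeros((20, 20, 20), dtype=np.uint8)
        expected[2:8, 2:7, 2:7] = 1
        assert np.array_equal(out.data, expected)
        # with min 10, both survive
        out2 = clusterize_segment(Volume(data), SegmentationParams(130, 10))
        assert out2.data.sum() == 200

    def test_uniform_subthreshold_empty(self):
        out = clusterize_segment(Volume(np.full((6, 6, 6), 10.0)), SegmentationParams(130, 1))
        assert out.data.sum() == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(4):
            data = rng.normal(100, 40, size=(14, 12, 13))
            params = SegmentationParams(threshold=130, min_cluster_voxels=4,
                                        connectivity=connectivity)
            got = clusterize_segment(Volume(data), params).data
            want = flood_fill_segment(data, 130, 4, connectivity)
            assert np.array_equal(got, want)

    def test_exclusion_mask_removes_region(self):
        data = np.full((10, 10, 10), 200.0)
        excl = np.zeros((10, 10, 10), dtype=np.uint8)
        excl[:5] = 1
        out = clusterize_segment(Volume(data), SegmentationParams(130, 1),
                                 exclusion_mask=Volume(excl))
        assert out.data[:5].sum() == 0 and out.data[5:].all()


class TestMapArithmetic:
    def test_mask_wmh_by_lesion_set_difference(self, rng):
        wmh = (rng.random((10, 10, 10)) > 0.5).astype(np.uint8)
        lesion = (rng.random((10, 10, 10)) > 0.5).astype(np.uint8)
        out = mask_wmh_by_lesion(Volume(wmh), Volume(lesion))
        assert np.array_equal(out.data, wmh & ~lesion & 1)
        assert not (out.data.astype(bool) & lesion.astype(bool)).any()

    def test_mask_disjoint_identity_and_subset_empty(self):
        wmh = np.zeros((6, 6, 6), dtype=np.uint8)
        wmh[0:2] = 1
        lesion = np.zeros_like(wmh)
        lesion[4:6] = 1
        assert np.array_equal(mask_wmh_by_lesion(Volume(wmh), Volume(lesion)).data, wmh)
        assert mask_wmh_by_lesion(Volume(wmh), Volume(wmh)).data.sum() == 0

    def test_split_hemispheres_partition(self, rng):
        data = (rng.random((12, 8, 8)) > 0.5).astype(np.uint8)
        left, right = split_hemispheres(Volume(data))
        assert not (left.data.astype(bool) & right.data.astype(bool)).any()
        assert np.array_equal(left.data | right.data, data)
        assert left.data[6:].sum() == 0 and right.data[:6].sum() == 0

    def test_split_mirrored_map_equal_counts(self):
        data = np.zeros((10, 6, 6), dtype=np.uint8)
        data[2, 1, 1] = data[7, 1, 1] = 1  # mirror about plane between 4 and 5
        left, right = split_hemispheres(Volume(data))
        assert left.data.sum() == right.data.sum() == 1

    def test_split_odd_nx_needs_midplane(self):
        vol = Volume(np.zeros((9, 4, 4)))
        with pytest.raises(VolumeError):
            split_hemispheres(vol)
        left, right = split_hemispheres(vol, midplane=4)
        assert left.shape == right.shape

    def test_volume_cm3(self):
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data.ravel()[:1000] = 1
        assert volume_cm3(Volume(data, voxel_size_mm=(1, 1, 1))) == pytest.approx(1.0)
        assert volume_cm3(Volume(np.zeros((4, 4, 4)))) == 0.0
        data2 = np.zeros((10, 10, 10), dtype=np.uint8)
        data2.ravel()[:500] = 1
        assert volume_cm3(Volume(data2, voxel_size_mm=(2, 2, 2))) == pytest.approx(4.0)
        with pytest.raises(VolumeError):
            volume_cm3(Volume(np.full((4, 4, 4), 2.0)))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(VolumeError):
            mask_wmh_by_lesion(Volume(np.zeros((4, 4, 4))), Volume(np.zeros((5, 4, 4))))
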
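"""Synthetic cohort generator: determinism, structural invariants,
calibration scales, rating reliability, and the FLAIR fixture."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from neglectwmh import (
    SimulationConfig,
    RandomStream,
    read_cohort,
    simulate_cohort,
    simulate_flair,
    simulate_ratings,
    weighted_kappa,
    write_cohort,
)
from neglectwmh.simulate import SimulationError
from neglectwmh.streams import FLAIR, RATING
from neglectwmh.volumes import SegmentationParams, Volume, clusterize_segment


class TestDeterminismAndInvariants:
    def test_same_seed_identical_cohort(self):
        cfg = SimulationConfig(n_patients=12, seed=42)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(c1.lesions, c2.lesions)
        assert np.array_equal(c1.wmhs, c2.wmhs)
        assert c1.table.equals(c2.table)

    def test_invariants_over_seed_sweep(self):
        for seed in range(30):
            c = simulate_cohort(SimulationConfig(n_patients=6, seed=seed))
            c.validate()  # right-hemisphere lesions, disjoint WMH, rating ranges
            nx = c.grid[0]
            assert not c.lesions[:, : nx // 2].any()
            assert not (c.lesions & c.wmhs).any()

    def test_lesions_connected(self):
        c = simulate_cohort(SimulationConfig(n_patients=8, seed=5))
        from scipy import ndimage
        for i in range(c.n):
            _, n_comp = ndimage.label(c.lesions[i])
            assert n_comp == 1

    def test_critical_region_must_be_right_hemisphere(self):
        bad = np.zeros((40, 48, 40), dtype=bool)
        bad[0:5, 20:25, 20:25] = True
        with pytest.raises(SimulationError):
            SimulationConfig(n_patients=5, critical_region=bad)


class TestCalibration:
    def test_volume_scales_match_clinical_anchors(self):
        # mean lesion volume within +-50% of 27.5 cm3, WMH within +-50% of 8.0 cm3
        les, wmh = [], []
        for seed in range(20):
            c = simulate_cohort(SimulationConfig(n_patients=103, seed=seed))
            les.append(c.table.lesion_volume_cm3.mean())
            wmh.append(c.table.wmh_volume_cm3.mean())
        assert 27.5 * 0.5 <= np.mean(les) <= 27.5 * 1.5
        assert 8.0 * 0.5 <= np.mean(wmh) <= 8.0 * 1.5

    def test_age_wmh_spearman_in_band(self):
        c = simulate_cohort(SimulationConfig(n_patients=500, seed=3))
        rs = spearmanr(c.table.age, c.table.wmh_volume_cm3).statistic
        assert 0.3 <= rs <= 0.6

    def test_null_betas_give_null_association(self):
        c = simulate_cohort(
            SimulationConfig(n_patients=500, seed=11, beta_lesion=0.0, beta_wmh=0.0)
        )
        coc = c.mean_coc()
        for col in ("right_wmh_volume_cm3", "lesion_volume_cm3", "age"):
            r = np.corrcoef(coc, c.table[col])[0, 1]
            assert abs(r) < 0.12  # sampling error only

    def test_wmh_effect_direction(self):
        on = simulate_cohort(SimulationConfig(n_patients=500, seed=2, beta_lesion=0.0))
        r_on = np.corrcoef(on.mean_coc(), on.table.right_wmh_volume_cm3)[0, 1]
        assert r_on > 0.2


class TestRatings:
    def test_zero_wmh_and_no_noise_all_zero(self):
        rng = np.random.default_rng(0)
        df = simulate_ratings(np.zeros(10), np.full(10, -5.0), np.full(10, -5.0), rng, 0.0)
        assert (df[["chs", "pv_wmh", "ds_wmh", "fazekas_total"]] == 0).all().all()

    def test_noiseless_ratings_monotone_in_severity(self):
        rng = np.random.default_rng(0)
        vols = np.array([0.5, 1.0, 3.0, 6.0, 12.0])
        lat = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        df = simulate_ratings(vols, lat, lat, rng, 0.0)
        for col in ("chs", "pv_wmh", "ds_wmh"):
            assert (np.diff(df[col]) >= 0).all()

    def test_two_raters_substantial_agreement(self):
        kappas = []
        for seed in range(20):
            c = simulate_cohort(SimulationConfig(n_patients=60, seed=seed))
            stream = RandomStream(c.config.seed)
            t = c.table
            r2 = simulate_ratings(
                t.wmh_volume_cm3.to_numpy(), t.pv_latent.to_numpy(),
                t.ds_latent.to_numpy(), stream.substream(RATING, 1), 0.5
            )
            kappas.append(weighted_kappa(t.chs.to_numpy(), r2.chs.to_numpy(), 10)[0])
        assert np.mean(kappas) > 0.6


class TestFlair:
    def test_segmentation_recovers_planted_union(self):
        c = simulate_cohort(SimulationConfig(n_patients=2, seed=9))
        stream = RandomStream(9)
        les, wmh = c.lesion_volume(0), c.wmh_volume(0)
        flair = simulate_flair(les, wmh, stream.substream(FLAIR, 0))
        seg = clusterize_segment(flair, SegmentationParams(130, 1))
        truth = (les.data | wmh.data).astype(bool)
        agreement = (seg.data.astype(bool) == truth).mean()
        assert agreement >= 0.99

    def test_same_stream_identical_volume(self):
        c = simulate_cohort(SimulationConfig(n_patients=1, seed=3))
        stream = RandomStream(3)
        f1 = simulate_flair(c.lesion_volume(0), c.wmh_volume(0), stream.substream(FLAIR, 0))
        f2 = simulate_flair(c.lesion_volume(0), c.wmh_volume(0), stream.substream(FLAIR, 0))
        assert np.array_equal(f1.data, f2.data)

    def test_empty_maps_no_large_clusters(self):
        empty = Volume(np.zeros((40, 48, 40), dtype=np.uint8), (2, 2, 2))
        stream = RandomStream(1)
        flair = simulate_flair(empty, empty, stream.substream(FLAIR, 5))
        seg = clusterize_segment(flair, SegmentationParams(130, 10))
        assert seg.data.sum() == 0


class TestCohortIO:
    def test_roundtrip_via_nifti_and_csv(self, tmp_path):
        c = simulate_cohort(SimulationConfig(n_patients=3, seed=1))
        write_cohort(c, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        assert np.array_equal(back.lesions, c.lesions)
        assert np.array_equal(back.wmhs, c.wmhs)
        assert np.allclose(back.table.letter_coc, c.table.letter_coc)
        assert back.voxel_size_mm == c.voxel_size_mm
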
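"""LGE threshold segmentation, label down-sampling, refinement, SNR."""

import numpy as np
import pytest

from dtbz.config import BACKGROUND, BZ, INFARCT, REMOTE
from dtbz.lge import (LGEVolume, LabelVolume, ROIStats, ThresholdSet,
                      classify_lge, compute_roi_stats, compute_snr,
                      derive_thresholds, downsample_labels, refine_labels)


def lge_from(si, voxdims=(1.0, 1.0, 1.0)):
    return LGEVolume(np.asarray(si, float), voxdims)


class TestROIStats:
    def test_constant_roi(self):
        vol = lge_from(np.full((4, 4, 1), 100.0))
        remote = np.zeros((4, 4, 1), bool); remote[:2] = True
        infarct = np.zeros((4, 4, 1), bool); infarct[2:] = True
        vol.si[infarct] = 300.0
        stats = compute_roi_stats(vol, remote, infarct)
        assert stats.mean_remote == 100.0 and stats.sd_remote == 0.0

    def test_hand_arithmetic(self):
        si = np.array([[[95.0, 100.0, 105.0, 295.0, 300.0, 305.0]]])
        vol = lge_from(si)
        remote = np.array([[[1, 1, 1, 0, 0, 0]]], bool)
        infarct = np.array([[[0, 0, 0, 1, 1, 1]]], bool)
        stats = compute_roi_stats(vol, remote, infarct)
        assert stats.mean_remote == 100.0 and stats.mean_infarct == 300.0
        assert stats.sd_remote == pytest.approx(5.0)
        assert stats.sd_infarct == pytest.approx(5.0)

    def test_inverted_means_raise(self):
        si = np.array([[[300.0, 100.0]]])
        vol = lge_from(si)
        with pytest.raises(ValueError, match="hyperenhancement"):
            compute_roi_stats(vol, np.array([[[1, 0]]], bool),
                              np.array([[[0, 1]]], bool))

    def test_overlapping_rois_raise(self):
        vol = lge_from(np.ones((2, 2, 1)))
        roi = np.ones((2, 2, 1), bool)
        with pytest.raises(ValueError, match="overlap"):
            compute_roi_stats(vol, roi, roi)


class TestThresholds:
    def test_printed_rule_arithmetic(self):
        thr = derive_thresholds(ROIStats(100.0, 5.0, 300.0, 5.0, 100, 100))
        assert thr.t_half == 200.0
        assert thr.t_bz == 110.0

    def test_zero_sd_floor_at_remote_mean(self):
        thr = derive_thresholds(ROIStats(100.0, 0.0, 300.0, 5.0, 100, 100))
        assert thr.t_bz == 100.0

    def test_inseparable_regions_raise(self):
        with pytest.raises(ValueError, match="separable"):
            derive_thresholds(ROIStats(100.0, 10.0, 120.0, 5.0, 100, 100))


class TestClassify:
    thr = ThresholdSet(t_half=200.0, t_bz=110.0)

    def test_rule_application(self):
        vol = lge_from(np.array([[[108.0, 150.0, 250.0]]]))
        lab = classify_lge(vol, np.ones((1, 1, 3), bool), self.thr).labels
        assert list(lab[0, 0]) == [REMOTE, BZ, INFARCT]

    def test_boundary_conventions(self):
        vol = lge_from(np.array([[[200.0, 110.0]]]))
        lab = classify_lge(vol, np.ones((1, 1, 2), bool), self.thr).labels
        assert lab[0, 0, 0] == INFARCT   # SI == t_half -> infarct
        assert lab[0, 0, 1] == REMOTE    # SI == t_bz -> remote

    def test_partition_of_myocardium(self, rng):
        si = rng.uniform(0, 400, (8, 8, 4))
        myo = rng.random((8, 8, 4)) > 0.4
        lab = classify_lge(lge_from(si), myo, self.thr).labels
        assert (lab[myo] != BACKGROUND).all()
        assert (lab[~myo] == BACKGROUND).all()

    def test_raising_t_half_never_grows_infarct(self, rng):
        si = rng.uniform(0, 400, (8, 8, 4))
        myo = np.ones((8, 8, 4), bool)
        lo = classify_lge(lge_from(si), myo, ThresholdSet(180.0, 110.0)).labels
        hi = classify_lge(lge_from(si), myo, ThresholdSet(260.0, 110.0)).labels
        assert (hi == INFARCT).sum() <= (lo == INFARCT).sum()


class TestDownsample:
    def test_uniform_block(self):
        src = np.full((6, 6, 18), INFARCT, dtype=np.int16)
        out = downsample_labels(LabelVolume(src, (1 / 3, 1 / 3, 1 / 3)),
                                (2, 2, 2), (1.0, 1.0, 3.0))
        assert (out.labels == INFARCT).all()

    def test_majority_block_oracle(self):
        """One 3x3x9 block, 60% infarct / 40% remote: majority wins."""
        block = np.full(27 * 3, REMOTE, dtype=np.int16)
        block[:int(81 * 0.6)] = INFARCT
        src = block.reshape(3, 3, 9)
        out = downsample_labels(LabelVolume(src, (1 / 3, 1 / 3, 1 / 3)),
                                (1, 1, 1), (1.0, 1.0, 3.0))
        assert out.labels[0, 0, 0] == INFARCT

    def test_background_passthrough(self):
        src = np.zeros((6, 6, 18), dtype=np.int16)
        out = downsample_labels(LabelVolume(src, (1 / 3, 1 / 3, 1 / 3)),
                                (2, 2, 2), (1.0, 1.0, 3.0))
        assert (out.labels == BACKGROUND).all()

    def test_non_integer_ratio_raises(self):
        src = np.zeros((7, 6, 18), dtype=np.int16)
        with pytest.raises(ValueError, match="integer multiple"):
            downsample_labels(LabelVolume(src, (1 / 3, 1 / 3, 1 / 3)),
                              (2, 2, 2), (1.0, 1.0, 3.0))


class TestRefine:
    @staticmethod
    def volume_with_island(n_voxels):
        lab = np.full((12, 12, 4), REMOTE, dtype=np.int16)
        coords = [(5, 5, 1), (5, 6, 1), (6, 5, 1), (6, 6, 1)][:n_voxels]
        for c in coords:
            lab[c] = INFARCT
        return LabelVolume(lab, (1.0, 1.0, 3.0))

    def test_three_voxel_island_removed_four_kept(self):
        out3 = refine_labels(self.volume_with_island(3))
        assert not (out3.labels == INFARCT).any()
        out4 = refine_labels(self.volume_with_island(4))
        assert (out4.labels == INFARCT).sum() == 4

    def test_bz_distance_pruning_matches_distance_oracle(self):
        lab = np.full((20, 20, 1), BZ, dtype=np.int16)
        lab[10, 10, 0] = INFARCT
        lab[10, 11, 0] = lab[11, 10, 0] = lab[11, 11, 0] = INFARCT  # 4-voxel, survives
        out = refine_labels(LabelVolume(lab, (1.0, 1.0, 3.0))).labels
        inf = np.argwhere(lab == INFARCT)
        for idx in np.argwhere(lab == BZ):
            d = np.sqrt(((idx - inf) ** 2).sum(axis=1)).min()
            expected = BZ if d <= 3.0 else REMOTE
            assert out[tuple(idx)] == expected

    def test_inplane_2mm_kept_4mm_pruned(self):
        lab = np.full((16, 16, 1), REMOTE, dtype=np.int16)
        lab[2:4, 2:4, 0] = INFARCT
        lab[3, 5, 0] = BZ   # 2 mm from infarct at (3, 3)
        lab[3, 7, 0] = BZ   # 4 mm away
        out = refine_labels(LabelVolume(lab, (1.0, 1.0, 3.0))).labels
        assert out[3, 5, 0] == BZ
        assert out[3, 7, 0] == REMOTE

    def test_no_infarct_clears_bz(self):
        lab = np.full((8, 8, 2), BZ, dtype=np.int16)
        out = refine_labels(LabelVolume(lab, (1.0, 1.0, 3.0)))
        assert not (out.labels == BZ).any()

    def test_idempotent(self, rng):
        lab = rng.choice([BACKGROUND, REMOTE, BZ, INFARCT],
                         size=(14, 14, 6)).astype(np.int16)
        once = refine_labels(LabelVolume(lab, (1.0, 1.0, 3.0)))
        twice = refine_labels(once)
        assert np.array_equal(once.labels, twice.labels)


class TestSNR:
    def test_arithmetic(self, rng):
        vol = np.zeros((10, 10, 1))
        tissue = np.zeros_like(vol, bool); tissue[:5] = True
        bg = np.zeros_like(vol, bool); bg[5:] = True
        vol[tissue] = 590.0
        vol[bg] = rng.normal(0, 10.0, int(bg.sum()))
        snr = compute_snr(vol, tissue, bg)
        assert snr == pytest.approx(590.0 / vol[bg].std(ddof=1))

    def test_constant_background_raises(self):
        vol = np.ones((4, 4, 1))
        t = np.zeros_like(vol, bool); t[:2] = True
        b = np.zeros_like(vol, bool); b[2:] = True
        with pytest.raises(ValueError, match="zero SD"):
            compute_snr(vol, t, b)

    def test_unequal_areas_raise(self):
        vol = np.ones((4, 4, 1))
        t = np.zeros_like(vol, bool); t[0] = True
        b = np.zeros_like(vol, bool); b[1:] = True
        with pytest.raises(ValueError, match="equal area"):
            compute_snr(vol, t, b)

    def test_phantom_snr_consistency(self, small_heart, small_spec):
        """The generator's measured SNRs track the spec values."""
        from dtbz.pipeline import measure_snr
        from dtbz.tensor import myocardium_mask_from_b0
        myo = myocardium_mask_from_b0(small_heart.dwi, 0.5)
        snr_dwi = measure_snr(small_heart.dwi.s0, myo)
        assert abs(snr_dwi - small_spec.dwi_snr) / small_spec.dwi_snr < 0.15
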
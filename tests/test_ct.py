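"""CT segmentation and per-slice coral content quantification."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from coralmound.ct import (
    CoreVolume,
    denoise,
    per_slice_content,
    quantify,
    segment_coral,
)


def _flood_fill_count(binary):
    """Brute-force 26-connected component count (oracle)."""
    labels, n = ndi.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    return n


class TestDenoise:
    def test_constant_volume_unchanged(self):
        vol = CoreVolume(np.full((8, 8, 8), 7.0))
        out = denoise(vol)
        assert np.allclose(out.voxels, 7.0)

    def test_h_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = CoreVolume(rng.normal(100, 5, (8, 8, 8)))
        out = denoise(vol, h=0)
        assert np.array_equal(out.voxels, vol.voxels)

    def test_noise_rmse_strictly_reduced(self):
        rng = np.random.default_rng(1)
        clean = np.full((16, 24, 24), 100.0)
        clean[:, 8:16, 8:16] = 200.0
        noisy = clean + rng.normal(0, 10, clean.shape)
        out = denoise(CoreVolume(noisy))
        rmse_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_after = np.sqrt(np.mean((out.voxels - clean) ** 2))
        assert rmse_after < rmse_before

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            denoise(CoreVolume(np.zeros((4, 4, 4))), patch_size=0)


class TestSegmentCoral:
    def test_all_below_threshold_gives_zero_labels(self):
        data = np.zeros((6, 6, 6))
        data[0, 0, 0] = 10.0
        voi = np.ones(data.shape, dtype=bool)
        voi[0, 0, 0] = False  # the only bright voxel is outside the VOI
        labels = segment_coral(CoreVolume(data, voi_mask=voi), threshold=5.0,
                               min_voxels=0)
        assert labels.max() == 0

    def test_threshold_outside_data_range_is_error(self):
        vol = CoreVolume(np.full((6, 6, 6), 1.0))
        with pytest.raises(ValueError, match="outside data range"):
            segment_coral(vol, threshold=99.0)

    def test_small_object_removed(self):
        data = np.zeros((8, 8, 8))
        data[2, 2, 2:6] = 10.0  # 4-voxel blob
        labels = segment_coral(CoreVolume(data), threshold=5.0)
        assert labels.max() == 0

    def test_five_voxel_object_survives(self):
        data = np.zeros((8, 8, 8))
        data[2, 2, 1:6] = 10.0  # exactly 5 voxels
        labels = segment_coral(CoreVolume(data), threshold=5.0)
        assert labels.max() >= 1
        assert (labels > 0).sum() == 5

    def test_two_separated_spheres_two_labels(self):
        data = np.zeros((24, 24, 24))
        zz, yy, xx = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        s1 = (zz - 6) ** 2 + (yy - 6) ** 2 + (xx - 6) ** 2 <= 9
        s2 = (zz - 17) ** 2 + (yy - 17) ** 2 + (xx - 17) ** 2 <= 9
        data[s1 | s2] = 10.0
        labels = segment_coral(CoreVolume(data), threshold=5.0)
        n_components = len(np.unique(labels)) - 1
        assert n_components == _flood_fill_count(data > 5.0) == 2

    def test_additive_intensity_shift_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 100, (10, 12, 12))
        l1 = segment_coral(CoreVolume(data), threshold=60.0)
        l2 = segment_coral(CoreVolume(data + 25.0), threshold=85.0)
        assert np.array_equal(l1 > 0, l2 > 0)

    def test_lower_threshold_never_decreases_content(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 100, (10, 16, 16))
        voi = np.ones(data.shape, dtype=bool)
        prev = None
        for thr in (80.0, 60.0, 40.0):
            labels = segment_coral(CoreVolume(data), threshold=thr, min_voxels=0)
            slices, _ = per_slice_content(labels, voi)
            pct = np.array([s.coral_percent for s in slices])
            if prev is not None:
                assert np.all(pct >= prev - 1e-12)
            prev = pct


class TestPerSliceContent:
    def test_no_labels_all_zero(self):
        labels = np.zeros((5, 6, 6), dtype=int)
        voi = np.ones_like(labels, dtype=bool)
        slices, summary = per_slice_content(labels, voi)
        assert all(s.coral_percent == 0.0 for s in slices)
        assert summary["mean_percent"] == 0.0

    def test_labels_equal_voi_all_hundred(self):
        voi = np.ones((5, 6, 6), dtype=bool)
        labels = voi.astype(int)
        slices, summary = per_slice_content(labels, voi)
        assert all(s.coral_percent == 100.0 for s in slices)
        assert summary["max_percent"] == 100.0

    def test_empty_voi_slice_is_missing(self):
        voi = np.ones((4, 6, 6), dtype=bool)
        voi[2] = False
        labels = np.zeros((4, 6, 6), dtype=int)
        slices, summary = per_slice_content(labels, voi)
        assert np.isnan(slices[2].coral_percent)
        assert summary["n_valid_slices"] == 3

    def test_output_bounded(self, small_phantom):
        vol, _ = small_phantom
        _, summary, labels = quantify(vol, denoise_first=False)
        pct = [s.coral_percent for s in per_slice_content(labels, vol.voi_mask)[0]]
        assert all(0.0 <= p <= 100.0 for p in pct if np.isfinite(p))


def test_phantom_recovery_within_two_points(small_phantom):
    """Full pipeline recovers the known per-slice coral fraction to +/- 2 pp."""
    vol, truth_percent = small_phantom
    slices, summary, _ = quantify(vol)
    est = np.array([s.coral_percent for s in slices])
    assert np.nanmax(np.abs(est - truth_percent)) <= 2.0
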
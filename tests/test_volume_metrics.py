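"""Volume I/O, preprocessing geometry, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conunet.metrics import dice_coefficient, evaluate, hd95, iou
from conunet.volume import (Volume, center_crop, load_volume,
                            resample_to_reference, save_volume, uncrop)


class TestVolume:
    def test_roundtrip_nifti(self, tmp_path):
        rng = np.random.default_rng(0)
        v = Volume(voxels=rng.random((4, 8, 6)).astype(np.float32),
                   spacing=(2.5, 0.7, 0.7), modality="PET")
        path = tmp_path / "vol.nii.gz"
        save_volume(v, path)
        back = load_volume(path)
        assert np.allclose(back.voxels, v.voxels)
        assert back.spacing == pytest.approx(v.spacing)
        assert back.modality == "PET"

    def test_mask_modality_roundtrip_and_binary(self, tmp_path):
        m = Volume(voxels=(np.arange(24).reshape(2, 3, 4) % 2).astype(np.uint8),
                   modality="mask")
        path = tmp_path / "mask.nii.gz"
        save_volume(m, path)
        back = load_volume(path)
        assert back.modality == "mask"
        assert np.array_equal(back.voxels, m.voxels)

    def test_validation(self):
        with pytest.raises(ValueError):
            Volume(voxels=np.zeros((2, 2)), modality="CT")
        with pytest.raises(ValueError):
            Volume(voxels=np.zeros((2, 2, 2)), spacing=(0, 1, 1))
        with pytest.raises(ValueError):
            Volume(voxels=np.full((2, 2, 2), 0.5), modality="mask")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope.nii.gz")


class TestResample:
    def test_doubles_grid_preserving_extent(self):
        v = Volume(voxels=np.ones((2, 256, 256), dtype=np.float32),
                   spacing=(1.0, 2.0, 2.0))
        out = resample_to_reference(v, spacing_mm=1.0, plane_size=512)
        assert out.voxels.shape == (2, 512, 512)
        assert out.spacing == (1.0, 1.0, 1.0)
        assert out.voxels.sum() == pytest.approx(2 * 512 * 512, rel=0.01)

    def test_conformant_volume_unchanged(self):
        rng = np.random.default_rng(1)
        v = Volume(voxels=rng.random((2, 512, 512)).astype(np.float32),
                   spacing=(1.0, 1.0, 1.0))
        out = resample_to_reference(v)
        assert np.allclose(out.voxels, v.voxels)

    def test_mask_stays_binary(self):
        m = Volume(voxels=(np.random.default_rng(2).random((2, 64, 64)) < 0.3
                           ).astype(np.uint8),
                   spacing=(1.0, 1.7, 1.7), modality="mask")
        out = resample_to_reference(m, plane_size=128)
        assert np.isin(out.voxels, (0, 1)).all()

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        v = Volume(voxels=rng.random((2, 200, 200)).astype(np.float32),
                   spacing=(1.0, 1.3, 1.3))
        once = resample_to_reference(v, plane_size=256)
        twice = resample_to_reference(once, plane_size=256)
        assert np.allclose(once.voxels, twice.voxels)


class TestCenterCrop:
    def test_512_to_288_offsets(self):
        v = Volume(voxels=np.zeros((1, 512, 512), dtype=np.float32))
        out = center_crop(v, 288)
        assert out.voxels.shape == (1, 288, 288)
        assert out.crop_offset == (112, 112)

    def test_crop_of_same_size_is_identity(self):
        rng = np.random.default_rng(4)
        v = Volume(voxels=rng.random((2, 64, 64)).astype(np.float32))
        out = center_crop(center_crop(v, 64), 64)
        assert np.array_equal(out.voxels, v.voxels)

    def test_uncrop_restores_geometry(self):
        rng = np.random.default_rng(5)
        v = Volume(voxels=rng.random((2, 100, 100)).astype(np.float32))
        cropped = center_crop(v, 60)
        restored = uncrop(cropped)
        assert restored.voxels.shape == v.voxels.shape
        top, left = cropped.crop_offset
        assert np.array_equal(restored.voxels[:, top:top + 60, left:left + 60],
                              cropped.voxels)
        outside = restored.voxels.copy()
        outside[:, top:top + 60, left:left + 60] = 0
        assert outside.sum() == 0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            center_crop(Volume(voxels=np.zeros((1, 64, 64))), 128)


def _hd95_bruteforce(a, b, spacing):
    """All-pairs symmetric surface-distance oracle."""
    from scipy.ndimage import binary_erosion

    def surf(m):
        pts = np.argwhere(m & ~binary_erosion(m, border_value=0))
        return pts * np.asarray(spacing)

    pa, pb = surf(a), surf(b)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return float(np.percentile(np.concatenate([d.min(1), d.min(0)]), 95))


class TestMetrics:
    def test_identical_masks(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:5, 3:6] = True
        assert dice_coefficient(m, m) == 1.0
        assert iou(m, m) == 1.0
        assert hd95(m, m) == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[0, 0] = b[7, 7] = True
        assert dice_coefficient(a, b) == 0.0
        assert iou(a, b) == 0.0

    def test_shifted_square_example(self):
        # 2x2 square vs the same square shifted one pixel: DSC 0.5, IoU 1/3
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[2:4, 2:4] = True
        b[2:4, 3:5] = True
        assert dice_coefficient(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(1.0 / 3.0)

    def test_empty_mask_conventions(self):
        empty = np.zeros((5, 5), dtype=bool)
        full = ~empty
        assert dice_coefficient(empty, empty) == 1.0
        assert iou(empty, empty) == 1.0
        assert dice_coefficient(empty, full) == 0.0
        # one-sided empty: HD95 reported as the image diagonal
        assert hd95(empty, full) == pytest.approx(np.sqrt(50))

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_iou_dsc_algebraic_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12)) < 0.3
        b = rng.random((12, 12)) < 0.3
        d = dice_coefficient(a, b)
        assert iou(a, b) == pytest.approx(d / (2.0 - d), abs=1e-12)

    def test_hd95_matches_bruteforce_oracle_on_32x32_masks(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = np.zeros((32, 32), dtype=bool)
            b = np.zeros((32, 32), dtype=bool)
            ya, xa = rng.integers(4, 20, 2)
            yb, xb = rng.integers(4, 20, 2)
            a[ya:ya + rng.integers(3, 10), xa:xa + rng.integers(3, 10)] = True
            b[yb:yb + rng.integers(3, 10), xb:xb + rng.integers(3, 10)] = True
            spacing = (1.0, 1.0)
            assert hd95(a, b, spacing) == pytest.approx(
                _hd95_bruteforce(a, b, spacing), abs=1e-9)

    def test_hd95_respects_spacing(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = b[0, 1] = True
        assert hd95(a, b, (1.0, 3.0)) == pytest.approx(3.0)


class TestEvaluate:
    def test_single_study(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        rep = evaluate([m], [m])
        assert rep.summary["dsc_mean"] == 1.0
        assert rep.summary["dsc_sd"] == 0.0
        assert len(rep.per_study) == 1

    def test_two_study_population_sd(self):
        # DSC 0.4 and 0.6 -> mean 0.5, population SD 0.1
        p1 = np.zeros(10, dtype=bool); t1 = np.zeros(10, dtype=bool)
        p1[:1] = True; t1[:4] = True      # 2*1 / (1+4) = 0.4
        p2 = np.zeros(10, dtype=bool); t2 = np.zeros(10, dtype=bool)
        p2[:4] = True; t2[1:7] = True     # 2*3 / (4+6) = 0.6
        rep = evaluate([p1, p2], [t1, t2])
        assert rep.summary["dsc_mean"] == pytest.approx(0.5)
        assert rep.summary["dsc_sd"] == pytest.approx(0.1)
        assert len(rep.per_study) == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([np.zeros((2, 2))], [])
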
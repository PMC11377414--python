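"""Tumor-area detection: rotation expansion, window selection, farthest
pairs, clustering and rectangle masking."""

import math

import numpy as np
import pytest

from conunet.detector import (NoTumorDetectedError, Quadruple, SliceSequence,
                              build_region_mask, cluster_quadruples,
                              expand_with_rotations, farthest_pair,
                              select_tsi_window, unrotate_sequence)


def _brute_force_farthest(mask):
    """O(n^2) oracle: scan every positive-pixel pair, exact int distances."""
    ys, xs = np.nonzero(np.asarray(mask) > 0)
    best, best_pair = -1, None
    pts = sorted(zip(xs.tolist(), ys.tolist()))
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            dx = pts[i][0] - pts[j][0]
            dy = pts[i][1] - pts[j][1]
            d2 = dx * dx + dy * dy
            pair = (pts[i], pts[j])
            if d2 > best or (d2 == best and pair < best_pair):
                best, best_pair = d2, pair
    return best_pair, math.sqrt(best)


class TestRotationExpansion:
    def test_three_slices_become_twelve_with_ordered_provenance(self):
        rng = np.random.default_rng(0)
        slices = [rng.random((6, 6)) for _ in range(3)]
        out = expand_with_rotations(slices)
        assert len(out) == 12
        assert out.provenance[5] == (1, 90)
        assert [p for p in out.provenance[:4]] == [(0, 0), (0, 90), (0, 180), (0, 270)]

    def test_unrotation_round_trips_every_entry(self):
        rng = np.random.default_rng(1)
        slices = [rng.random((8, 8)) for _ in range(4)]
        out = expand_with_rotations(slices)
        back = unrotate_sequence(out)
        for s, (src, _) in zip(back.slices, back.provenance):
            assert np.array_equal(s, slices[src])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            expand_with_rotations([np.zeros((4, 6))])


class TestWindowSelection:
    def _masks(self, flags, size=8):
        return [np.full((size, size), int(f), dtype=np.uint8) for f in flags]

    def test_40_consecutive_positive_slices_give_21(self):
        masks = self._masks([False] * 5 + [True] * 40 + [False] * 5)
        assert len(select_tsi_window(masks)) == 21

    def test_short_run_clips_to_run(self):
        masks = self._masks([False, True, True, True, True, True, False])
        assert select_tsi_window(masks) == [1, 2, 3, 4, 5]

    def test_run_0_to_20_selects_everything(self):
        masks = self._masks([True] * 21)
        assert select_tsi_window(masks) == list(range(21))

    def test_window_never_exceeds_21(self):
        for n in (1, 10, 21, 22, 60, 101):
            masks = self._masks([True] * n)
            assert len(select_tsi_window(masks)) == min(n, 21)

    def test_longest_run_wins(self):
        masks = self._masks([True] * 3 + [False] * 2 + [True] * 9)
        idx = select_tsi_window(masks)
        assert min(idx) >= 5  # anchored on the 9-run, not the 3-run

    def test_all_empty_raises(self):
        with pytest.raises(NoTumorDetectedError):
            select_tsi_window(self._masks([False] * 4))


class TestFarthestPair:
    def test_three_point_example(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        for x, y in [(0, 0), (3, 4), (1, 1)]:
            mask[y, x] = 1
        q = farthest_pair(mask)
        assert (q.x_l, q.y_l, q.x_r, q.y_r) == (0, 0, 3, 4)
        assert q.distance == pytest.approx(5.0)

    def test_two_pixel_mask_returns_that_pair(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1, 2] = mask[4, 0] = 1
        q = farthest_pair(mask)
        assert {(q.x_l, q.y_l), (q.x_r, q.y_r)} == {(2, 1), (0, 4)}

    def test_fewer_than_two_pixels_rejected(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            farthest_pair(mask)
        mask[2, 2] = 1
        with pytest.raises(ValueError):
            farthest_pair(mask)

    def test_matches_brute_force_oracle_on_50_random_masks(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            mask = rng.random((20, 20)) < rng.uniform(0.02, 0.3)
            if mask.sum() < 2:
                mask[0, 0] = mask[5, 7] = True
            q = farthest_pair(mask)
            (pl, pr), dist = _brute_force_farthest(mask)
            assert ((q.x_l, q.y_l), (q.x_r, q.y_r)) == (pl, pr)
            assert q.distance == pytest.approx(dist)

    def test_180_rotation_symmetry(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            mask = (rng.random((15, 15)) < 0.1)
            if mask.sum() < 2:
                continue
            q = farthest_pair(mask)
            qr = farthest_pair(np.rot90(mask, 2))
            n = 15 - 1
            mapped = sorted([(n - q.x_l, n - q.y_l), (n - q.x_r, n - q.y_r)])
            got = sorted([(qr.x_l, qr.y_l), (qr.x_r, qr.y_r)])
            assert mapped == got
            assert qr.distance == pytest.approx(q.distance)


class TestClustering:
    def _quad(self, x, y, spread=0):
        return Quadruple(x_l=x, y_l=y, x_r=x + 5 + spread, y_r=y + 3,
                         distance=0.0)

    def test_two_repeated_quadruples_recover_centers_exactly(self):
        quads = [self._quad(10, 10)] * 2 + [self._quad(100, 100)] * 2
        res = cluster_quadruples(quads, seed=0)
        centers = sorted(res.centers.tolist())
        assert centers[0] == [10, 10, 15, 13]
        assert centers[1] == [100, 100, 105, 103]
        assert sorted(res.sizes) == [2, 2]

    def test_gaussian_blobs_recovered_within_2px(self):
        rng = np.random.default_rng(21)
        quads = []
        for cx in (50, 150):
            for _ in range(10):
                x, y = rng.normal([cx, cx], 1.0)
                quads.append(Quadruple(x_l=int(round(x)), y_l=int(round(y)),
                                       x_r=int(round(x)) + 4, y_r=int(round(y)),
                                       distance=4.0))
        res = cluster_quadruples(quads, seed=0)
        got = sorted(c[0] for c in res.centers)
        assert abs(got[0] - 50) < 2 and abs(got[1] - 150) < 2

    def test_permutation_invariance_up_to_label_swap(self):
        rng = np.random.default_rng(22)
        quads = [self._quad(int(x), int(y)) for x, y in
                 rng.uniform(0, 100, size=(20, 2))]
        a = cluster_quadruples(quads, seed=0)
        order = rng.permutation(len(quads))
        b = cluster_quadruples([quads[i] for i in order], seed=0)
        assert np.allclose(sorted(a.centers.tolist()), sorted(b.centers.tolist()))

    def test_single_quadruple_falls_back_to_one_cluster(self):
        res = cluster_quadruples([self._quad(5, 5)], seed=0)
        assert res.sizes == (1, 0)
        assert np.allclose(res.centers[0], res.centers[1])


class TestRegionMask:
    def test_spec_rectangle_arithmetic(self):
        quads = [Quadruple(100, 100, 120, 110, 0.0)] * 3
        res = cluster_quadruples(quads, seed=0)
        region = build_region_mask(res, lam=50, image_shape=(288, 288),
                                   quads=quads)
        rows, cols = np.nonzero(region.mask)
        assert (cols.min(), cols.max()) == (50, 170)
        assert (rows.min(), rows.max()) == (50, 160)
        assert region.mask.sum() == (170 - 50 + 1) * (160 - 50 + 1)

    def test_degenerate_single_pixel(self):
        quads = [Quadruple(7, 9, 7, 9, 0.0)]
        res = cluster_quadruples(quads, seed=0)
        region = build_region_mask(res, lam=0, image_shape=(20, 20), quads=quads)
        assert region.mask.sum() == 1 and region.mask[9, 7] == 1

    def test_border_clipping(self):
        quads = [Quadruple(2, 3, 5, 4, 0.0)] * 2
        res = cluster_quadruples(quads, seed=0)
        region = build_region_mask(res, lam=50, image_shape=(30, 30), quads=quads)
        assert region.mask.sum() == 30 * 30  # padding swallows the whole image

    def test_majority_cluster_selected(self):
        quads = ([Quadruple(10, 10, 14, 12, 0.0)] * 5
                 + [Quadruple(200, 200, 204, 202, 0.0)] * 2)
        res = cluster_quadruples(quads, seed=0)
        region = build_region_mask(res, lam=5, image_shape=(256, 256), quads=quads)
        rows, cols = np.nonzero(region.mask)
        assert cols.max() < 30 and rows.max() < 30


def _distractor_study():
    """A phantom whose distractor blob sits well away from the tumor run."""
    from conunet.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(image_size=(64, 64), n_slices=40,
                       tumor_radius_range=(4.0, 6.0), distractor_prob=1.0)
    study = generate_phantom(spec, np.random.default_rng(78))
    assert study.distractor_center is not None
    return study


class ThresholdModel:
    """Controlled predictor: marks every pixel brighter than `level` as tumor.

    Fires on the tumor and on the sub-tumor-intensity distractor alike, which
    is exactly the failure mode the area detector exists to clean up (the
    distractor crosses the level only through its noise tail); using
    it isolates the detector's algorithmic behavior from the quality of a
    trained network.
    """

    def __init__(self, level: float = 0.6):
        self.level = level

    def __call__(self, x):
        from conunet.model import ConnectedOutput

        x = np.asarray(x)
        return ConnectedOutput(pseudo_pet=np.zeros_like(x),
                               seg_prob=(x > self.level).astype(np.float32))


class TestRefine:
    def test_rectangle_localizes_tumor_and_confines_prediction(self):
        """The detected rectangle lands on the tumor; nothing survives
        outside it."""
        from conunet.detector import refine

        study = _distractor_study()
        refined = refine(ThresholdModel(), study.ct, lam=12, seed=0)
        assert refined.shape == study.ct.voxels.shape
        assert refined.sum() > 0  # tumor retained
        rows = np.nonzero(refined.any(axis=(0, 2)))[0]
        cols = np.nonzero(refined.any(axis=(0, 1)))[0]
        # tumor radius <= 6 px and lambda = 12: the occupied box stays small
        assert rows.max() - rows.min() <= 2 * (6 + 12)
        assert cols.max() - cols.min() <= 2 * (6 + 12)

    def test_distractor_positives_removed(self):
        """A distant blob that fools the first pass is gone after refinement."""
        from conunet.detector import refine
        from conunet.trainer import predict

        study = _distractor_study()
        model = ThresholdModel()
        _, _, first_pass = predict(model, study.ct.voxels)
        dz, dy, dx = study.distractor_center
        near = slice(max(0, int(dx) - 8), int(dx) + 9)
        assert first_pass[:, :, near].sum() > 0  # first pass is fooled
        refined = refine(model, study.ct, lam=12, seed=0)
        tumor_cols = np.nonzero(study.mask.voxels.any(axis=(0, 1)))[0]
        lo, hi = tumor_cols.min() - 14, tumor_cols.max() + 14
        outside = np.ones(64, dtype=bool)
        outside[max(0, lo):hi + 1] = False
        assert refined[:, :, outside].sum() == 0
        assert refined.sum() > 0

    def test_all_ones_region_leaves_prediction_unchanged(self):
        """With the region mask forced to cover everything, re-prediction
        reproduces the unrefined prediction."""
        from conunet.detector import refine
        from conunet.trainer import predict

        study = _distractor_study()
        model = ThresholdModel()
        _, _, unrefined = predict(model, study.ct.voxels)
        refined = refine(model, study.ct, lam=10_000, seed=0)  # U covers all
        assert np.array_equal(refined, unrefined)

    def test_trained_model_refinement_confined_to_region(self, training_run):
        """End-to-end with the trained network: refined positives stay inside
        the rectangle the pipeline detected."""
        from conunet.detector import refine
        from conunet.trainer import predict

        from conunet.detector import (cluster_quadruples, farthest_pair,
                                      select_tsi_window)

        checkpoint, _, _ = training_run
        study = _distractor_study()
        model = checkpoint.build_model()
        refined = refine(model, study.ct, lam=12, seed=0)
        assert refined.sum() > 0
        # recompute the rectangle with the same pipeline pieces; every refined
        # positive must lie inside it
        expanded = expand_with_rotations(study.ct.voxels)
        _, _, tsi = predict(model, np.stack(expanded.slices))
        seq = unrotate_sequence(SliceSequence(slices=list(tsi),
                                              provenance=expanded.provenance))
        window = select_tsi_window(seq)
        quads = [farthest_pair(seq.slices[i], source_slice=i) for i in window
                 if (np.asarray(seq.slices[i]) > 0).sum() >= 2]
        region = build_region_mask(cluster_quadruples(quads, seed=0), 12,
                                   (64, 64), quads=quads)
        assert (refined * (1 - region.mask[None])).sum() == 0

    def test_no_tumor_detected_propagates(self):
        from conunet.detector import refine
        from conunet.model import ConnectedOutput

        class SilentModel:
            """Stand-in network that never predicts tumor."""

            def __call__(self, x):
                x = np.asarray(x)
                return ConnectedOutput(pseudo_pet=np.zeros_like(x),
                                       seg_prob=np.zeros_like(x))

        flat = np.zeros((4, 64, 64), dtype=np.float32)
        with pytest.raises(NoTumorDetectedError):
            refine(SilentModel(), flat, lam=12, seed=0)
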
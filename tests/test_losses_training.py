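"""Composed loss, pixel weighting, schedule, augmentation, splits, training."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from obseg.errors import ParameterError
from obseg.image_io import LabelMap, VolumeImage, default_affine
from obseg.losses_training import (AugmentConfig, SlicePairDataset, TrainConfig,
                                   boundary_weight_map, composed_loss,
                                   intensity_augment, lr_schedule,
                                   make_stratified_splits, spatial_augment,
                                   train_view_model)
from obseg.networks import segmentation_spec


class TestBoundaryWeights:
    def test_single_class_slice_is_uniform_one(self):
        w = boundary_weight_map(np.zeros((8, 8), np.int16))
        np.testing.assert_array_equal(w, np.ones((8, 8)))

    def test_median_frequency_interior_weights(self):
        # 90/10 split: median freq 0.5 -> weights 0.5/0.9 and 0.5/0.1
        lab = np.zeros((10, 10), np.int16)
        lab[0, :] = 1  # 10 of 100 pixels
        w = boundary_weight_map(lab, edge_weight=0.0)
        assert w[5, 5] == pytest.approx(0.5 / 0.9)
        assert w[0, 0] == pytest.approx(5.0)

    def test_isolated_pixel_edge_bonus_covers_neighbourhood(self):
        lab = np.zeros((9, 9), np.int16)
        lab[4, 4] = 1
        w = boundary_weight_map(lab)
        interior = np.median(np.unique(w))
        bonus_region = w > w[0, 0]  # strictly above the plain background weight
        expected = np.zeros((9, 9), bool)
        expected[3:6, 3:6] = True
        np.testing.assert_array_equal(bonus_region, expected)


class TestComposedLoss:
    def test_perfect_prediction_reaches_lower_bound(self):
        g = np.zeros((2, 4, 4))
        g[0, :2] = 1
        g[1, 2:] = 1
        assert composed_loss(g.copy(), g) == pytest.approx(-2.0, abs=1e-6)

    def test_single_pixel_hand_computed_value(self):
        # p=(0.5, 0.5), truth class 1, w=1, gamma=2:
        # focal 0.25*ln 2, dice 0 - 0.5/0.625 -> total about -0.626713
        p = np.array([[[0.5]], [[0.5]]])
        g = np.array([[[0.0]], [[1.0]]])
        expected = 0.25 * math.log(2.0) - 0.8
        assert composed_loss(p, g) == pytest.approx(expected, abs=1e-6)
        assert composed_loss(p, g) == pytest.approx(-0.626713, abs=1e-6)

    def test_loss_decreases_as_confidence_grows(self):
        losses = []
        for pt in (0.5, 0.9, 0.99):
            p = np.array([[[1 - pt]], [[pt]]])
            g = np.array([[[0.0]], [[1.0]]])
            losses.append(composed_loss(p, g))
        assert losses[0] > losses[1] > losses[2]

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            composed_loss(np.array([[[1.5]], [[-0.5]]]),
                          np.array([[[1.0]], [[0.0]]]))

    def test_matches_straight_line_oracle_on_random_slabs(self, rng):
        for _ in range(25):
            logits = rng.standard_normal((2, 4, 4))
            e = np.exp(logits)
            p = e / e.sum(axis=0, keepdims=True)
            cls = rng.integers(0, 2, (4, 4))
            g = np.stack([cls == 0, cls == 1]).astype(float)
            w = rng.random((4, 4)) + 0.5
            # independent straight-line evaluation
            eps = 1e-7
            pc = np.clip(p, eps, 1 - eps)
            focal = float((w * ((1 - pc) ** 2 * g * -np.log(pc)).sum(axis=0)).sum())
            dice_t = sum(2 * (p[l] * g[l]).sum()
                         / ((p[l] ** 2).sum() + (g[l] ** 2).sum())
                         for l in range(2))
            expected = focal - dice_t
            assert composed_loss(p, g, w) == pytest.approx(expected, abs=1e-6)

    def test_lower_bound_property(self, rng):
        for _ in range(10):
            logits = rng.standard_normal((2, 3, 3))
            e = np.exp(logits)
            p = e / e.sum(axis=0, keepdims=True)
            cls = rng.integers(0, 2, (3, 3))
            g = np.stack([cls == 0, cls == 1]).astype(float)
            assert composed_loss(p, g) >= -2.0


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [(0, 0.01), (4, 0.01),
                                                (5, 0.0095), (12, 0.009025)])
    def test_step_decay(self, epoch, expected):
        assert lr_schedule(epoch, TrainConfig()) == pytest.approx(expected)

    def test_invariant_formula(self):
        cfg = TrainConfig()
        for e in range(0, 40, 7):
            assert lr_schedule(e, cfg) == pytest.approx(
                cfg.lr0 * 0.95 ** (e // 5))


def _blob_pair(radius=10, shape=(48, 48, 48), vox=1.0):
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    c = (np.array(shape) - 1) / 2
    blob = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= radius ** 2
    vol = VolumeImage(blob.astype(np.float32) * 0.8 + 0.1, default_affine(vox))
    lab = LabelMap(blob.astype(np.int16), default_affine(vox), codes=(0, 1))
    return vol, lab


class TestSpatialAugment:
    def test_identity_parameters_change_nothing(self):
        vol, lab = _blob_pair()
        params = {"translation_mm": np.zeros(3), "rotation_deg": np.zeros(3),
                  "scale": 1.0}
        v2, l2, _ = spatial_augment(vol, lab, params=params)
        np.testing.assert_array_equal(l2.data, lab.data)
        np.testing.assert_allclose(v2.data, vol.data, atol=1e-6)

    def test_label_codes_closed_under_augmentation(self, rng):
        vol, lab = _blob_pair()
        _, l2, _ = spatial_augment(vol, lab, rng=rng)
        assert set(np.unique(l2.data)) <= set(np.unique(lab.data))

    def test_rotation_round_trip_keeps_blob(self):
        from obseg.evaluation import dice
        vol, lab = _blob_pair(radius=20, shape=(64, 64, 64))
        fwd = {"translation_mm": np.zeros(3),
               "rotation_deg": np.array([0.0, 0.0, 10.0]), "scale": 1.0}
        back = {"translation_mm": np.zeros(3),
                "rotation_deg": np.array([0.0, 0.0, -10.0]), "scale": 1.0}
        _, l1, _ = spatial_augment(vol, lab, params=fwd)
        _, l2, _ = spatial_augment(vol, l1, params=back)
        assert dice(lab.data, l2.data) >= 0.95


class TestIntensityAugment:
    def test_output_stays_non_negative(self, rng):
        vol, _ = _blob_pair()
        out, _ = intensity_augment(vol, rng=rng)
        assert (out.data >= 0).all()

    def test_parameters_reusable_at_subject_level(self, rng):
        vol, _ = _blob_pair()
        out1, params = intensity_augment(vol, rng=rng)
        out2, _ = intensity_augment(vol, params=params)
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_blur_preserves_mean_away_from_borders(self):
        vol = VolumeImage(np.full((40, 40, 40), 0.6, np.float32),
                          default_affine(1.0))
        vol.data[15:25, 15:25, 15:25] = 0.9
        out, _ = intensity_augment(vol, params={"bias": None, "blur_sigma": 1.0})
        assert abs(out.data.mean() - vol.data.mean()) / vol.data.mean() < 0.02


class TestStratifiedSplits:
    def _table(self):
        rows = []
        for i in range(16):
            rows.append({"id": f"s{i:02d}", "age": 30 + 40 * (i % 2),
                         "sex": "f" if i < 8 else "m"})
        return pd.DataFrame(rows)

    def test_perfectly_balanced_case(self):
        plan = make_stratified_splits(self._table(), k=4, seed=0)
        for g in range(4):
            members = plan.members(g)
            assert len(members) == 4
            assert len({plan.strata[m] for m in members}) == 4

    def test_disjoint_and_exhaustive(self):
        plan = make_stratified_splits(self._table(), k=4, seed=1)
        all_ids = sorted(m for g in range(4) for m in plan.members(g))
        assert all_ids == sorted(self._table()["id"])

    def test_seed_determinism(self):
        t = self._table()
        a = make_stratified_splits(t, k=4, seed=5)
        b = make_stratified_splits(t, k=4, seed=5)
        c = make_stratified_splits(t, k=4, seed=6)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            make_stratified_splits(pd.DataFrame(columns=["id", "age", "sex"]))


class TestTrainViewModel:
    def _tiny_dataset(self):
        vol, lab = _blob_pair(radius=4, shape=(16, 16, 16), vox=0.8)
        return SlicePairDataset([(vol, lab)], crop_size=None)

    def _cfg(self, seed=0):
        return TrainConfig(epochs=2, batch_size=4, filters=8, augment=False,
                           seed=seed)

    def test_best_checkpoint_is_argmax_of_history(self):
        trained = train_view_model(self._tiny_dataset(), "axial",
                                   segmentation_spec(filters=8), self._cfg())
        assert trained.best_val_dice == trained.history["val_dice"].max()

    def test_identical_seeds_reproduce_identical_histories(self):
        a = train_view_model(self._tiny_dataset(), "axial",
                             segmentation_spec(filters=8), self._cfg(seed=3))
        b = train_view_model(self._tiny_dataset(), "axial",
                             segmentation_spec(filters=8), self._cfg(seed=3))
        pd.testing.assert_frame_equal(a.history, b.history)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ParameterError):
            SlicePairDataset([], crop_size=None)
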
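"""Unit and property tests for the overlap metrics and smoothed Dice loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fpnseg import metrics
from fpnseg.metrics import (
    ConfusionCounts,
    confusion_counts,
    dice_loss,
    dsc,
    jaccard,
    pixel_accuracy,
    score_mask_files,
)

from conftest import random_binary_pair


def disjoint_pair(n_each=50, shape=(10, 10)):
    pred = np.zeros(shape, np.uint8)
    ref = np.zeros(shape, np.uint8)
    pred.flat[:n_each] = 1
    ref.flat[n_each : 2 * n_each] = 1
    return pred, ref


class TestDiceLoss:
    def test_identity_is_zero(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[5:25, 5:30] = 1
        assert mask.sum() == 500
        assert dice_loss(mask, mask, xi=100.0) == pytest.approx(0.0, abs=1e-12)

    def test_both_empty_is_zero(self):
        z = np.zeros((8, 8), np.uint8)
        assert dice_loss(z, z, xi=100.0) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_50_50_xi_100(self):
        # hand evaluation: 1 - (0 + 100)/(50 + 50 + 100) = 0.5
        pred, ref = disjoint_pair(50)
        assert dice_loss(pred, ref, xi=100.0) == pytest.approx(0.5, abs=1e-12)

    def test_soft_prediction_uses_products(self):
        ref = np.zeros((4, 4), np.float64)
        ref[:2] = 1.0
        pred = np.full((4, 4), 0.5)
        inter = (pred * ref).sum()
        expected = 1.0 - (2 * inter + 10.0) / (pred.sum() + ref.sum() + 10.0)
        assert dice_loss(pred, ref, xi=10.0) == pytest.approx(expected, abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            pred, ref = random_binary_pair(rng)
            val = dice_loss(pred, ref)
            assert 0.0 <= val <= 1.0

    def test_zero_iff_identical_hard_masks(self, rng):
        for _ in range(100):
            pred, ref = random_binary_pair(rng)
            loss = dice_loss(pred, ref, xi=50.0)
            if np.array_equal(pred, ref):
                assert loss == pytest.approx(0.0, abs=1e-12)
            else:
                assert loss > 0.0

    def test_xi_to_zero_approaches_one_minus_dsc(self, rng):
        for _ in range(20):
            pred, ref = random_binary_pair(rng)
            if pred.sum() + ref.sum() == 0:
                continue
            assert dice_loss(pred, ref, xi=1e-9) == pytest.approx(
                1.0 - dsc(pred, ref), abs=1e-9
            )

    @pytest.mark.parametrize("bad_xi", [-1.0, -1e-9])
    def test_negative_xi_rejected(self, bad_xi):
        z = np.zeros((4, 4), np.uint8)
        with pytest.raises(ValueError):
            dice_loss(z, z, xi=bad_xi)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        mask = (rng.random((12, 12)) < 0.4).astype(np.uint8)
        assert dsc(mask, mask) == 1.0
        assert jaccard(mask, mask) == 1.0

    def test_disjoint_masks(self):
        pred, ref = disjoint_pair(30)
        assert dsc(pred, ref) == 0.0
        assert jaccard(pred, ref) == 0.0

    def test_half_overlap(self):
        # |A| = |B| = 100, |A∩B| = 50 -> DSC 0.5, Jaccard 1/3
        pred = np.zeros((20, 20), np.uint8)
        ref = np.zeros((20, 20), np.uint8)
        pred.flat[:100] = 1
        ref.flat[50:150] = 1
        assert dsc(pred, ref) == pytest.approx(0.5, abs=1e-12)
        assert jaccard(pred, ref) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_both_empty_convention(self):
        z = np.zeros((6, 6), np.uint8)
        assert dsc(z, z) == 1.0
        assert jaccard(z, z) == 1.0

    def test_symmetry(self, rng):
        for _ in range(100):
            pred, ref = random_binary_pair(rng)
            assert dsc(pred, ref) == pytest.approx(dsc(ref, pred), abs=1e-15)
            assert jaccard(pred, ref) == pytest.approx(jaccard(ref, pred), abs=1e-15)

    def test_jaccard_dsc_identity_and_ordering(self, rng):
        for _ in range(300):
            pred, ref = random_binary_pair(rng)
            d = dsc(pred, ref)
            j = jaccard(pred, ref)
            assert j == pytest.approx(d / (2.0 - d), abs=1e-12)
            assert j <= d + 1e-15

    def test_soft_input_rejected_for_hard_metrics(self):
        with pytest.raises(ValueError):
            dsc(np.full((4, 4), 0.5), np.zeros((4, 4)))

    @settings(max_examples=200, derandomize=True)
    @given(
        pred=hnp.arrays(np.uint8, (9, 9), elements=st.integers(0, 1)),
        ref=hnp.arrays(np.uint8, (9, 9), elements=st.integers(0, 1)),
        xi=st.floats(0.1, 200.0),
    )
    def test_metric_relations_hold_for_arbitrary_masks(self, pred, ref, xi):
        d = dsc(pred, ref)
        j = jaccard(pred, ref)
        assert j == pytest.approx(d / (2.0 - d), abs=1e-12)
        assert 0.0 <= j <= d <= 1.0
        loss = dice_loss(pred, ref, xi=xi)
        assert 0.0 <= loss <= 1.0
        if np.array_equal(pred, ref):
            assert loss == pytest.approx(0.0, abs=1e-12)


class TestConfusionCounts:
    def test_all_ones(self):
        ones = np.ones((5, 5), np.uint8)
        counts = confusion_counts(ones, ones)
        assert counts == ConfusionCounts(tp=25, tn=0, fp=0, fn=0)

    def test_all_missed(self):
        pred = np.zeros((5, 5), np.uint8)
        ref = np.ones((5, 5), np.uint8)
        assert confusion_counts(pred, ref) == ConfusionCounts(tp=0, tn=0, fp=0, fn=25)

    def test_matches_per_pixel_loop_oracle(self, rng):
        for _ in range(50):
            pred, ref = random_binary_pair(rng, shape=(8, 8))
            counts = confusion_counts(pred, ref)
            tp = tn = fp = fn = 0
            for i in range(8):
                for j in range(8):
                    if ref[i, j] and pred[i, j]:
                        tp += 1
                    elif not ref[i, j] and not pred[i, j]:
                        tn += 1
                    elif not ref[i, j] and pred[i, j]:
                        fp += 1
                    else:
                        fn += 1
            assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)
            assert counts.total == 64


class TestPixelAccuracy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(10, 90, 0, 0), 1.0),
            (ConfusionCounts(0, 0, 50, 50), 0.0),
            (ConfusionCounts(30, 50, 10, 10), 0.8),
        ],
    )
    def test_values(self, counts, expected):
        assert pixel_accuracy(counts) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pixel_accuracy(ConfusionCounts(0, 0, 0, 0))


class TestScoreFiles:
    def test_scoring_entry_point(self, tmp_path, rng):
        from PIL import Image

        pred, ref = random_binary_pair(rng, shape=(32, 32))
        ppath = tmp_path / "pred.png"
        rpath = tmp_path / "ref.png"
        Image.fromarray(pred * 255).save(ppath)
        Image.fromarray(ref * 255).save(rpath)
        result = score_mask_files(ppath, rpath)
        assert result["dsc"] == pytest.approx(dsc(pred, ref), abs=1e-12)
        assert result["jaccard"] == pytest.approx(jaccard(pred, ref), abs=1e-12)
        assert result["accuracy"] == pytest.approx(
            pixel_accuracy(confusion_counts(pred, ref)), abs=1e-12
        )

    def test_default_smoothing_value(self):
        assert metrics.DEFAULT_SMOOTHING == 100.0
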
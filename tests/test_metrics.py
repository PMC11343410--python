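import numpy as np
import pytest

from conftest import brute_force_contingency, random_label_pair
from nucseg.metrics import (
    MatchResult,
    MetricConfig,
    adapted_f1,
    conventional_f1,
    dataset_score,
    evaluate_batch,
    evaluate_pair,
    f1_curve,
    match_objects,
    object_iou_by_size,
    pairwise_iou,
    split_merge_rate,
)


def shifted_square_pair(shift=2):
    gt = np.zeros((30, 30), dtype=np.int32)
    gt[5:15, 5:15] = 1
    pred = np.zeros_like(gt)
    pred[5 + shift : 15 + shift, 5:15] = 1
    return gt, pred


class TestPairwiseIOU:
    def test_identical_masks(self, small_mask):
        t = pairwise_iou(small_mask, small_mask)
        assert len(t.iou) == small_mask.max()
        np.testing.assert_allclose(t.iou, 1.0)

    def test_disjoint_objects_empty_table(self):
        gt = np.zeros((10, 10), dtype=int)
        gt[:3, :3] = 1
        pred = np.zeros_like(gt)
        pred[6:, 6:] = 1
        t = pairwise_iou(gt, pred)
        assert len(t.iou) == 0
        assert t.n_gt == 1 and t.n_pred == 1

    def test_shifted_square_exact_fraction(self):
        t = pairwise_iou(*shifted_square_pair(2))
        assert t.intersection[0] == 80
        assert t.union[0] == 120

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_iou(np.zeros((3, 3), int), np.zeros((4, 4), int))


class TestMatchObjects:
    def cfg(self, tau1=0.6):
        return MetricConfig(tau1=tau1)

    def test_perfect_match(self, small_mask):
        m = evaluate_pair(small_mask, small_mask, self.cfg())
        n = small_mask.max()
        assert (m.tp, m.fp, m.fn, m.ia, m.splits, m.merges) == (n, 0, 0, 0, 0, 0)

    def test_five_px_shift_is_ia(self):
        m = evaluate_pair(*shifted_square_pair(5), self.cfg())
        assert (m.tp, m.fp, m.fn, m.ia) == (0, 0, 0, 1)

    def test_merge_counts_two_ia_one_merge(self):
        gt = np.zeros((30, 40), dtype=int)
        gt[5:15, 5:15] = 1
        gt[5:15, 15:25] = 2
        pred = np.zeros_like(gt)
        pred[5:15, 5:25] = 1     # covers both; each pair IOU = 100/200 = 0.5
        m = evaluate_pair(gt, pred, self.cfg())
        assert m.merges == 1
        assert m.ia == 2
        assert m.fp == 0

    def test_zero_overlap_counts_fp_and_fn(self):
        gt = np.zeros((20, 20), dtype=int)
        gt[:5, :5] = 1
        pred = np.zeros_like(gt)
        pred[10:15, 10:15] = 1
        m = evaluate_pair(gt, pred, self.cfg())
        assert m.fn == 1 and m.fp == 1

    def test_low_tau1_warns_and_uses_greedy(self):
        t = pairwise_iou(*shifted_square_pair(2))
        with pytest.warns(UserWarning, match="greedy"):
            match_objects(t, MetricConfig(tau1=0.4))

    def test_agrees_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            gt, pred = random_label_pair(rng)
            expected = brute_force_contingency(gt, pred)
            m = evaluate_pair(gt, pred, self.cfg())
            got = dict(tp=m.tp, fp=m.fp, fn=m.fn, ia=m.ia, splits=m.splits,
                       merges=m.merges, n_gt=m.n_gt, n_pred=m.n_pred)
            assert got == expected

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        gt, pred = random_label_pair(rng)
        perm = rng.permutation(np.arange(1, pred.max() + 1))
        relabeled = np.zeros_like(pred)
        for old, new in enumerate(perm, start=1):
            relabeled[pred == old] = new
        a = evaluate_pair(gt, pred, self.cfg())
        b = evaluate_pair(gt, relabeled, self.cfg())
        assert (a.tp, a.fp, a.fn, a.ia, a.splits, a.merges) == (
            b.tp, b.fp, b.fn, b.ia, b.splits, b.merges
        )


class TestF1Scores:
    def test_conventional_worked_example(self):
        m = MatchResult(tp=1, fp=0, fn=0, ia=0, splits=0, merges=0, n_gt=1, n_pred=2)
        # FP_conv = n_pred - TP = 1, FN_conv = n_gt - TP = 0
        assert conventional_f1(m, eps=0) == pytest.approx(2 / 3)

    def test_adapted_worked_example_tp1_ia1(self):
        m = MatchResult(tp=1, fp=0, fn=0, ia=1, splits=0, merges=0, n_gt=2, n_pred=2)
        eps = 1e-8
        assert adapted_f1(m, eps) == pytest.approx(2 / (3 + eps))
        assert conventional_f1(m, eps) == pytest.approx(2 / (4 + eps))

    def test_zero_tp_scores_zero(self):
        m = MatchResult(tp=0, fp=1, fn=1, ia=0, splits=0, merges=0, n_gt=1, n_pred=1)
        assert adapted_f1(m) == 0.0
        assert conventional_f1(m) == 0.0

    def test_adapted_at_least_conventional_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            gt, pred = random_label_pair(rng)
            m = evaluate_pair(gt, pred)
            assert adapted_f1(m) >= conventional_f1(m) - 1e-12

    def test_partition_identity_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            gt, pred = random_label_pair(rng)
            m = evaluate_pair(gt, pred)
            assert m.tp + m.fn + m.ia + m.splits == m.n_gt


class TestF1Curve:
    def test_perfect_match_all_ones(self, small_mask):
        curve = f1_curve(small_mask, small_mask)
        assert (curve["adapted_f1"] > 0.999).all()
        assert (curve["conventional_f1"] > 0.999).all()

    def test_shifted_square_threshold_crossing(self):
        gt, pred = shifted_square_pair(2)  # IOU = 2/3
        curve = f1_curve(gt, pred).set_index("tau1")
        for t1 in (0.5, 0.55, 0.6, 0.65):
            assert curve.loc[t1, "adapted_f1"] > 0.99  # TP: IOU 2/3 > tau1
        for t1 in (0.7, 0.75, 0.8, 0.85, 0.9):
            # above 2/3 the object becomes an IA; with no TP both F1s vanish
            assert curve.loc[t1, "adapted_f1"] == 0.0
            assert curve.loc[t1, "conventional_f1"] == 0.0

    def test_non_increasing_in_tau1(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            gt, pred = random_label_pair(rng)
            curve = f1_curve(gt, pred)
            for col in ("adapted_f1", "conventional_f1"):
                assert (np.diff(curve[col]) <= 1e-12).all()


class TestDatasetScore:
    def mk(self, tp, fp, fn, ia, n_gt, n_pred):
        return MatchResult(tp=tp, fp=fp, fn=fn, ia=ia, splits=0, merges=0,
                           n_gt=n_gt, n_pred=n_pred)

    def test_single_image_avg_equals_agg(self):
        m = self.mk(2, 1, 0, 1, 3, 3)
        assert dataset_score([m], "avg") == pytest.approx(dataset_score([m], "agg"))

    def test_avg_is_plain_mean(self):
        a = self.mk(1, 0, 0, 1, 2, 1)    # adapted = 2/3
        b = self.mk(1, 0, 0, 0, 1, 1)    # adapted = 1
        assert dataset_score([a, b], "avg") == pytest.approx((2 / 3 + 1) / 2, abs=1e-6)

    def test_avg_differs_from_agg_with_unbalanced_images(self):
        tiny = self.mk(0, 0, 1, 0, 1, 0)          # score 0, one object
        big = self.mk(99, 0, 0, 1, 100, 99)       # score ~0.995
        avg = dataset_score([tiny, big], "avg")
        agg = dataset_score([tiny, big], "agg")
        assert avg == pytest.approx((0 + 2 * 99 / (2 * 99 + 1)) / 2, abs=1e-6)
        assert agg == pytest.approx(2 * 99 / (2 * 99 + 1 + 1), abs=1e-6)
        assert abs(avg - agg) > 0.2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            dataset_score([], "avg")


class TestSplitMergeRate:
    def mk(self, splits, merges, n_gt, n_pred):
        tp = n_gt - splits
        return MatchResult(tp=tp, fp=0, fn=0, ia=0, splits=splits, merges=merges,
                           n_gt=n_gt, n_pred=n_pred)

    def test_no_errors_rate_zero(self):
        r = split_merge_rate([self.mk(0, 0, 10, 10)])
        assert r["split_rate_mean"] == 0 and r["merge_rate_mean"] == 0

    def test_two_splits_in_100_gt(self):
        r = split_merge_rate([self.mk(2, 0, 100, 102)])
        assert r["split_rate_mean"] == pytest.approx(1.0)  # per 50 GT nuclei

    def test_zero_denominator_excluded_and_reported(self):
        empty = MatchResult(tp=0, fp=0, fn=0, ia=0, splits=0, merges=0,
                            n_gt=0, n_pred=0)
        r = split_merge_rate([empty, self.mk(1, 1, 50, 50)])
        assert r["excluded_split_images"] == 1
        assert r["split_rate_mean"] == pytest.approx(1.0)


class TestObjectIOUBySize:
    def test_cutoff_boundary_in_physical_units(self):
        # 3001 px at 0.5 um/px -> 750.25 um^2 -> large; 3000 px -> 750.0 -> small
        gt = np.zeros((200, 100), dtype=int)
        gt[:30, :100] = 1           # 3000 px
        gt[100 : 100 + 30, :100] = 2
        gt[130, 0] = 2              # 3001 px
        cfg = MetricConfig(pixel_size_um=0.5)
        res = object_iou_by_size(gt, gt, cfg)
        assert res["n_large"] == 1 and res["n_small"] == 1

    def test_perfect_prediction_scores_one(self, small_mask):
        cfg = MetricConfig(pixel_size_um=10.0)  # everything large
        res = object_iou_by_size(small_mask, small_mask, cfg)
        assert res["large_mean_iou"] == pytest.approx(1.0)

    def test_empty_prediction_scores_zero(self, small_mask):
        cfg = MetricConfig(pixel_size_um=10.0)
        res = object_iou_by_size(small_mask, np.zeros_like(small_mask), cfg)
        assert res["large_mean_iou"] == 0.0

    def test_missing_pixel_size_rejected(self, small_mask):
        with pytest.raises(ValueError):
            object_iou_by_size(small_mask, small_mask, MetricConfig())


class TestEvaluateBatch:
    def test_summary_consistent_with_per_image(self, small_mask):
        rng = np.random.default_rng(3)
        pairs = [random_label_pair(rng) for _ in range(5)]
        per_image, summary = evaluate_batch(pairs)
        head = summary[np.isclose(summary["tau1"], 0.6)].iloc[0]
        assert head["adapted_f1_avg"] == pytest.approx(per_image["adapted_f1"].mean())
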
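"""Metrics against oracles, the split protocol, ablation harness, separability."""

import numpy as np
import pandas as pd
import pytest

from protods import (
    ImbalanceSpec,
    balanced_accuracy,
    build_imbalanced_split,
    confusion,
    macro_ap,
    macro_auroc,
    macro_f1,
    sens_spec,
    separability_iou,
)
from protods.errors import InputError, UndefinedMetricError


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cm = confusion([1, 2, 3, 1], [1, 2, 3, 1])
        np.testing.assert_array_equal(cm.matrix, np.diag([2, 1, 1]))

    def test_hand_counted_binary_matrix(self):
        # class 2 positive: TP=2, FP=1, FN=1, TN=6
        true = [2, 2, 2] + [1] * 7
        pred = [2, 2, 1] + [2] + [1] * 6
        cm = confusion(true, pred)
        np.testing.assert_array_equal(cm.matrix, [[6, 1], [1, 2]])
        tp, fp, fn, tn = cm.one_vs_rest(1)
        assert (tp, fp, fn, tn) == (2, 1, 1, 6)

    def test_order_invariance(self, rng):
        true = rng.integers(1, 4, 30)
        pred = rng.integers(1, 4, 30)
        perm = rng.permutation(30)
        np.testing.assert_array_equal(
            confusion(true, pred).matrix, confusion(true[perm], pred[perm]).matrix
        )

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(InputError):
            confusion([1, 2], [1, 3], class_ids=[1, 2])


class TestScalarMetrics:
    def test_balanced_accuracy_mean_of_recalls(self):
        cm = confusion([1, 1, 2, 2], [1, 1, 2, 1])  # recalls 1.0 and 0.5
        assert balanced_accuracy(cm) == pytest.approx(0.75)

    def test_binary_bacc_equals_mean_sens_spec(self, rng):
        true = rng.integers(1, 3, 50)
        pred = rng.integers(1, 3, 50)
        cm = confusion(true, pred, class_ids=[1, 2])
        if cm.matrix.sum(axis=1).min() == 0:
            pytest.skip("degenerate draw")
        ss = sens_spec(cm)
        sens, spec = ss[2]  # class 2 as positive
        assert balanced_accuracy(cm) == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_macro_f1_matches_loop_oracle(self, rng):
        true = rng.integers(1, 5, 60)
        pred = rng.integers(1, 5, 60)
        cm = confusion(true, pred, class_ids=[1, 2, 3, 4])
        f1s = []
        for k in [1, 2, 3, 4]:
            tp = np.sum((true == k) & (pred == k))
            prec = tp / max(np.sum(pred == k), 1)
            rec = tp / np.sum(true == k)
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
        assert macro_f1(cm) == pytest.approx(np.mean(f1s), abs=1e-12)

    def test_empty_true_class_is_undefined(self):
        cm = confusion([1, 1], [1, 2], class_ids=[1, 2])
        with pytest.raises(UndefinedMetricError):
            balanced_accuracy(cm)


class TestRankingMetrics:
    def test_perfect_separation(self):
        labels = [1, 1, 2, 2]
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert macro_auroc(scores, labels) == pytest.approx(1.0)
        assert macro_ap(scores, labels) == pytest.approx(1.0)

    def test_anti_ordered_scores_give_zero_auroc(self):
        labels = [1, 1, 2, 2]
        scores = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        assert macro_auroc(scores, labels) == pytest.approx(0.0)

    def test_matches_all_pairs_oracle_with_midrank_ties(self, rng):
        """AUROC equals the mean over (pos, neg) pairs of [s_p > s_n] + 0.5[s_p = s_n]."""
        labels = rng.integers(1, 4, 120)
        scores = np.round(rng.random((120, 3)), 2)  # rounding forces ties
        got = macro_auroc(scores, labels, class_ids=[1, 2, 3])
        aucs = []
        for j, k in enumerate([1, 2, 3]):
            pos = scores[labels == k, j]
            neg = scores[labels != k, j]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            aucs.append((wins + 0.5 * ties) / (pos.size * neg.size))
        assert got == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(123)
        labels = rng.integers(1, 3, 200)
        scores = rng.random((200, 2))
        assert abs(macro_auroc(scores, labels) - 0.5) < 0.1

    def test_single_class_labels_undefined(self):
        with pytest.raises(UndefinedMetricError):
            macro_auroc(np.random.rand(5, 2), [1, 1, 1, 1, 1], class_ids=[1, 2])


def _manifest(counts: dict[int, int]) -> pd.DataFrame:
    rows = []
    for label, n in counts.items():
        for j in range(n):
            rows.append({"instance_id": f"c{label}_{j}", "label": label,
                         "cube_path": ""})
    return pd.DataFrame(rows)


class TestImbalancedSplit:
    @pytest.mark.parametrize(
        "n, expected",
        [(1, (5, 3, 1)), (5, (25, 13, 5)), (20, (99, 52, 20))],
    )
    def test_ratio_scaling_with_half_up_rounding(self, n, expected):
        # original counts emulate a 4-class age-graded dataset: 1267/197/104/40
        manifest = _manifest({1: 1267, 2: 197, 3: 104, 4: 40})
        train, _ = build_imbalanced_split(manifest, ImbalanceSpec(n=n, seed=0))
        counts = train["label"].value_counts()
        assert (counts[2], counts[3], counts[4]) == expected
        assert counts[1] == 634  # majority training kept whole (half-up of 633.5)

    def test_binary_minority_exact_majority_untouched(self):
        manifest = _manifest({1: 305, 2: 235})
        spec = ImbalanceSpec(n=20, train_fraction=0.8, seed=1)
        train, test = build_imbalanced_split(manifest, spec)
        counts = train["label"].value_counts()
        assert counts[2] == 20
        assert counts[1] == int(np.floor(0.8 * 305))
        assert len(test) == 305 + 235 - int(np.floor(0.8 * 305)) - int(np.floor(0.8 * 235))

    def test_test_set_invariant_across_n(self):
        manifest = _manifest({1: 100, 2: 60})
        tests = []
        for n in (1, 5, 20):
            _, test = build_imbalanced_split(manifest, ImbalanceSpec(n=n, seed=3))
            tests.append(sorted(test["instance_id"]))
        assert tests[0] == tests[1] == tests[2]

    def test_requesting_more_than_available_raises(self):
        manifest = _manifest({1: 10, 2: 4})
        with pytest.raises(InputError):
            build_imbalanced_split(manifest, ImbalanceSpec(n=3, train_fraction=0.5))


class TestSeparabilityIOU:
    def test_identical_distributions_overlap_fully(self, rng):
        pts = rng.standard_normal((300, 5))
        labels = np.r_[np.ones(150, int), np.full(150, 2)]
        iou, proj = separability_iou(pts, labels)
        assert proj.shape == (300, 2)
        assert iou[0, 1] > 0.8  # sampling noise keeps it just below 1

    def test_far_separated_clusters_have_zero_iou(self, rng):
        a = rng.standard_normal((100, 4))
        b = rng.standard_normal((100, 4)) + 100.0
        iou, _ = separability_iou(np.vstack([a, b]), np.r_[np.ones(100, int), np.full(100, 2)])
        assert iou[0, 1] == 0.0

    def test_grid_refinement_converges(self, rng):
        a = rng.standard_normal((100, 3))
        b = rng.standard_normal((100, 3)) + 1.5
        x = np.vstack([a, b])
        labels = np.r_[np.ones(100, int), np.full(100, 2)]
        coarse, _ = separability_iou(x, labels, resolution=200)
        fine, _ = separability_iou(x, labels, resolution=400)
        assert abs(coarse[0, 1] - fine[0, 1]) <= 0.01

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(InputError):
            separability_iou(rng.random((4, 3)), [1, 1, 2, 2])


class TestRunAblation:
    def test_single_cell_grid_and_determinism(self, small_dataset, tiny_net_cfg):
        from protods import FinetuneConfig, SSLConfig
        from protods.evaluation import run_ablation

        _, train, test, band_idx = small_dataset
        from protods import NetworkConfig

        net_cfg = NetworkConfig(input_dim=band_idx.size, hidden_dim=16, n_blocks=1)
        kwargs = dict(
            net_cfg=net_cfg, ssl_cfg=SSLConfig(epochs=1),
            ft_cfg=FinetuneConfig(epochs=1), variants=["no_ssl_no_dice"], seeds=[0],
        )
        a = run_ablation(train, test, **kwargs)
        b = run_ablation(train, test, **kwargs)
        assert len(a) == 1
        assert (a["error"] == "").all()
        pd.testing.assert_frame_equal(a, b)


def test_balanced_accuracy_prevalence_invariance(rng):
    """Duplicating every majority test instance leaves B.Acc unchanged."""
    true = np.array([1] * 20 + [2] * 5)
    pred = rng.integers(1, 3, 25)
    base = balanced_accuracy(confusion(true, pred, class_ids=[1, 2]))
    dup_true = np.concatenate([true, true[:20]])
    dup_pred = np.concatenate([pred, pred[:20]])
    doubled = balanced_accuracy(confusion(dup_true, dup_pred, class_ids=[1, 2]))
    assert doubled == pytest.approx(base, abs=1e-12)
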
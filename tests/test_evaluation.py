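"""Metric suite vs independent oracles; interval estimators."""

import numpy as np
import pytest
from scipy import stats

from gaitshift.conditions import CLASS_ORDER
from gaitshift.evaluation import (
    ConfusionMatrix,
    aggregate_metrics,
    bootstrap_interval,
    class_leakage,
    classwise_metrics,
    confusion_matrix,
    evaluate_predictions,
    summarise_folds,
    t_interval,
    wilson_interval,
)


def _brute_force_classwise(counts):
    """Loop-over-cells one-vs-rest oracle, independent of the implementation."""
    k = len(counts)
    out = {"precision": [], "recall": [], "specificity": [], "f1": []}
    for c in range(k):
        tp = fp = fn = tn = 0
        for i in range(k):
            for j in range(k):
                n = counts[i][j]
                if i == c and j == c:
                    tp += n
                elif j == c:
                    fp += n
                elif i == c:
                    fn += n
                else:
                    tn += n
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        for key, val in zip(out, (prec, rec, spec, f1)):
            out[key].append(val)
    return out


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        y = list(CLASS_ORDER) * 3
        cm = confusion_matrix(y, y)
        assert (cm.counts == np.eye(6) * 3).all()

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion_matrix([], [])
        assert cm.counts.sum() == 0

    def test_hand_counted_example(self):
        true = ["none", "none", "green", "green", "blue", "blue",
                "black", "red", "red", "orange", "orange", "orange"]
        pred = ["none", "green", "green", "blue", "blue", "green",
                "black", "red", "orange", "orange", "orange", "red"]
        cm = confusion_matrix(true, pred)
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1
        assert cm.counts[1, 1] == 1 and cm.counts[1, 2] == 1
        assert cm.counts[2, 2] == 1 and cm.counts[2, 1] == 1
        assert cm.counts[3, 3] == 1
        assert cm.counts[4, 4] == 1 and cm.counts[4, 5] == 1
        assert cm.counts[5, 5] == 2 and cm.counts[5, 4] == 1
        assert cm.total == 12

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion_matrix(["none"], ["violet"])

    def test_integer_labels_accepted(self):
        cm = confusion_matrix([0, 5], [5, 0])
        assert cm.counts[0, 5] == 1 and cm.counts[5, 0] == 1


class TestClasswiseAndAggregates:
    def test_perfect_diagonal_gives_all_ones(self):
        cm = ConfusionMatrix(np.eye(6, dtype=int) * 7)
        cw = classwise_metrics(cm)
        for arr in (cw.precision, cw.recall, cw.specificity, cw.f1):
            np.testing.assert_allclose(arr, 1.0)
        agg = aggregate_metrics(cm)
        assert agg.class_balance_pp == 0.0
        assert agg.avg_fpr == 0.0
        assert agg.leakage == []

    def test_never_predicted_class_has_zero_precision_and_recall(self):
        counts = np.eye(6, dtype=int) * 5
        counts[2, 2] = 0
        counts[2, 1] = 5  # 'blue' always predicted as 'green'
        cw = classwise_metrics(ConfusionMatrix(counts))
        assert cw.precision[2] == 0.0
        assert cw.recall[2] == 0.0

    def test_oracle_equivalence_on_random_matrices(self, rng):
        for _ in range(300):
            counts = rng.integers(0, 60, size=(6, 6))
            cm = ConfusionMatrix(counts)
            cw = classwise_metrics(cm)
            oracle = _brute_force_classwise(counts.tolist())
            np.testing.assert_allclose(cw.precision, oracle["precision"])
            np.testing.assert_allclose(cw.recall, oracle["recall"])
            np.testing.assert_allclose(cw.specificity, oracle["specificity"])
            np.testing.assert_allclose(cw.f1, oracle["f1"])

    def test_matches_sklearn_on_random_labelings(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            t = rng.integers(0, 6, 300)
            p = rng.integers(0, 6, 300)
            cm = confusion_matrix(t, p)
            agg = aggregate_metrics(cm)
            assert agg.accuracy == pytest.approx(sk.accuracy_score(t, p))
            assert agg.weighted_f1 == pytest.approx(
                sk.f1_score(t, p, average="weighted", zero_division=0))
            assert agg.avg_f1 == pytest.approx(
                sk.f1_score(t, p, average="macro", zero_division=0))

    def test_aggregate_identities_on_random_matrices(self, rng):
        for _ in range(100):
            cm = ConfusionMatrix(rng.integers(1, 50, size=(6, 6)))
            cw = classwise_metrics(cm)
            agg = aggregate_metrics(cm)
            assert agg.accuracy == pytest.approx(
                np.trace(cm.counts) / cm.counts.sum())
            assert cw.f1.min() - 1e-12 <= agg.weighted_f1 <= cw.f1.max() + 1e-12
            assert agg.min_recall == pytest.approx(cw.recall.min())
            assert agg.class_balance_pp == pytest.approx(
                100 * (cw.recall.max() - cw.recall.min()))
            assert agg.avg_fpr == pytest.approx((1 - cw.specificity).mean())


class TestLeakage:
    def test_constructed_24_percent_leak(self):
        counts = np.eye(6, dtype=int) * 100
        counts[2, 1] = 32  # 32 / (100+32+1) ~ 24%
        counts[2, 0] = 1
        lk = class_leakage(ConfusionMatrix(counts), top_k=2)
        assert lk[0] == ("blue", "green", 24)

    def test_ties_break_by_class_order(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 1] = counts[1, 0] = 50
        counts[0, 0] = counts[1, 1] = 50
        lk = class_leakage(ConfusionMatrix(counts), top_k=2)
        assert lk == [("none", "green", 50), ("green", "none", 50)]


class TestWilson:
    def test_upper_bound_exactly_one_at_p_hat_one(self):
        ci = wilson_interval(1.0, 50)
        assert ci.upper == pytest.approx(1.0)
        assert ci.lower < 1.0

    def test_matches_closed_form(self):
        p, n = 0.5, 200
        z = stats.norm.ppf(0.975)
        centre = (p + z * z / (2 * n)) / (1 + z * z / n)
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
        ci = wilson_interval(p, n)
        assert ci.lower == pytest.approx(centre - half)
        assert ci.upper == pytest.approx(centre + half)

    def test_matches_statsmodels(self):
        proportion = pytest.importorskip("statsmodels.stats.proportion")
        for p_hat, n in [(0.7136, 8406), (0.1, 50), (0.95, 300)]:
            lo, hi = proportion.proportion_confint(round(p_hat * n), n,
                                                   method="wilson")
            ci = wilson_interval(round(p_hat * n) / n, n)
            assert ci.lower == pytest.approx(lo, abs=1e-10)
            assert ci.upper == pytest.approx(hi, abs=1e-10)

    def test_asymptotic_half_width(self):
        p, n = 0.3, 2_000_000
        ci = wilson_interval(p, n)
        half_pp = (ci.upper_offset_pp - ci.lower_offset_pp) / 2
        wald = 100 * stats.norm.ppf(0.975) * np.sqrt(p * (1 - p) / n)
        assert half_pp == pytest.approx(wald, rel=0.01)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0.5, 0)


def _accuracy(t, p):
    return (np.asarray(t) == np.asarray(p)).mean()


class TestBootstrap:
    def test_perfect_predictions_give_zero_width(self):
        y = np.array([0, 1, 2, 3, 4, 5] * 10)
        ci = bootstrap_interval(y, y, _accuracy, B=100, seed=0)
        assert ci.lower_offset_pp == 0.0
        assert ci.upper_offset_pp == 0.0
        assert ci.point == 1.0

    def test_offsets_stable_in_B(self, rng):
        t = rng.integers(0, 6, 1000)
        p = np.where(rng.random(1000) < 0.7, t, rng.integers(0, 6, 1000))
        c1 = bootstrap_interval(t, p, _accuracy, B=500, seed=3)
        c2 = bootstrap_interval(t, p, _accuracy, B=1000, seed=3)
        assert abs(c1.lower_offset_pp - c2.lower_offset_pp) < 1.0
        assert abs(c1.upper_offset_pp - c2.upper_offset_pp) < 1.0

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_interval([0], [0], _accuracy, B=1)


class TestFoldSummary:
    def test_identical_folds_collapse_to_zero_width(self):
        fs = summarise_folds({"accuracy": [0.5] * 5})
        m = fs.metrics["accuracy"]
        assert m["std"] == 0.0 and m["ci_half_width"] == 0.0

    def test_two_folds_use_t_quantile_12_706(self):
        mean, std, half = t_interval([0.6, 0.8])
        assert mean == pytest.approx(0.7)
        assert std == pytest.approx(np.sqrt(0.02))
        assert half == pytest.approx(12.706204736 * std / np.sqrt(2), rel=1e-6)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            summarise_folds({"accuracy": [0.5]})


class TestReport:
    def test_report_schema_complete(self, rng):
        t = rng.integers(0, 6, 400)
        p = np.where(rng.random(400) < 0.6, t, rng.integers(0, 6, 400))
        rep = evaluate_predictions(t, p, seed=1, bootstrap_B=50)
        d = rep.to_dict()
        for key in ("accuracy", "weighted_f1", "min_recall", "avg_f1",
                    "class_balance_pp", "avg_fpr", "leakage",
                    "accuracy_ci_pp", "min_recall_ci_pp"):
            assert key in d
        assert len(d["confusion_matrix"]) == 6
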
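import math

import numpy as np
import pytest

from targetddi import classifier, evaluation
from targetddi.evaluation import (ConfusionMatrix, confusion, f1_positive,
                                  overall_metrics, per_class_metrics, roc_auc)
from targetddi.io import NEGATIVE, POSITIVE, InteractionSet
from targetddi.profiles import build_design_matrix, build_universe

# ---------------------------------------------------------------------------
# sklearn-free brute-force oracle, computed directly from label lists
# ---------------------------------------------------------------------------

def _oracle_counts(y_true, y_pred):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == -1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == -1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == -1 and p == -1)
    return tp, fn, fp, tn


def _div(a, b):
    return a / b if b else math.nan


def _oracle_metrics(y_true, y_pred):
    tp, fn, fp, tn = _oracle_counts(y_true, y_pred)
    n = tp + fn + fp + tn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc_cls = _div(tp * tn - fp * fn, den) if den else math.nan
    pr_pos, se_pos = _div(tp, tp + fp), _div(tp, tp + fn)
    # F1 as the literal harmonic mean of PR and SE: undefined whenever PR is
    # undefined (no positive predictions) or PR + SE = 0
    if math.isnan(pr_pos) or math.isnan(se_pos) or pr_pos + se_pos == 0:
        f1 = math.nan
    else:
        f1 = 2 * pr_pos * se_pos / (pr_pos + se_pos)
    return {
        "pr_pos": pr_pos, "se_pos": se_pos,
        "pr_neg": _div(tn, tn + fn), "se_neg": _div(tn, tn + fp),
        "mcc_pos": mcc_cls, "mcc_neg": mcc_cls,
        "acc": (tp + tn) / n,
        # pooled intermediates of the 2x2 matrix: p = q = diagonal sum,
        # r = s = off-diagonal sum
        "mcc": _div((tp + tn) - (fp + fn), n),
        "f1": f1,
    }


def _oracle_auc(y_true, scores):
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == -1]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0)
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def _assert_close_or_both_nan(a, b, tol=1e-12):
    if math.isnan(b):
        assert math.isnan(a)
    else:
        assert abs(a - b) <= tol


class TestConfusion:
    def test_perfect_diagonal(self):
        cm = confusion([1] * 10 + [-1] * 10, [1] * 10 + [-1] * 10)
        assert cm.m.tolist() == [[10, 0], [0, 10]]

    def test_all_predicted_positive(self):
        cm = confusion([1] * 5 + [-1] * 5, [1] * 10)
        assert cm.m.tolist() == [[5, 0], [5, 0]]

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            confusion([], [])

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            confusion([1, -1], [1])


class TestMetricFormulas:
    # true-positive row (50 right, 10 leaked), true-negative row (5, 35)
    CM = ConfusionMatrix(np.array([[50, 10], [5, 35]]))

    def test_per_class_precision_sensitivity(self):
        pcm = per_class_metrics(self.CM)
        assert pcm["PR"][0] == pytest.approx(50 / 55)
        assert pcm["SE"][0] == pytest.approx(50 / 60)

    def test_accuracy(self):
        acc, _ = overall_metrics(self.CM)
        assert acc == pytest.approx(0.85)

    def test_f1_hand_arithmetic(self):
        pr, se = 50 / 55, 50 / 60
        assert f1_positive(self.CM) == pytest.approx(2 * pr * se / (pr + se))

    def test_perfect_matrix(self):
        cm = ConfusionMatrix(np.array([[7, 0], [0, 3]]))
        pcm = per_class_metrics(cm)
        assert pcm["PR"] == (1.0, 1.0) and pcm["SE"] == (1.0, 1.0)
        assert pcm["MCC"][0] == pytest.approx(1.0)
        acc, _ = overall_metrics(cm)
        assert acc == 1.0
        assert f1_positive(cm) == 1.0

    def test_never_predicted_class_gives_na(self):
        cm = ConfusionMatrix(np.array([[5, 0], [5, 0]]))
        pcm = per_class_metrics(cm)
        assert math.isnan(pcm["PR"][1])  # negative class never predicted

    def test_f1_undefined_when_precision_or_sum_degenerate(self):
        # nothing predicted positive: PR+ is 0/0 -> NA propagates to F1
        cm = ConfusionMatrix(np.array([[0, 5], [0, 5]]))
        assert math.isnan(f1_positive(cm))
        # PR+ = SE+ = 0: harmonic mean has zero denominator -> NA
        cm2 = ConfusionMatrix(np.array([[0, 5], [5, 5]]))
        assert math.isnan(f1_positive(cm2))

    def test_brute_force_oracle_random_instances(self):
        """Confusion-matrix formulas match direct label-list arithmetic."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 60))
            y_true = rng.choice([1, -1], size=n)
            y_pred = rng.choice([1, -1], size=n)
            if len(set(y_true.tolist())) < 2:
                y_true[0] = -y_true[0]
            cm = confusion(y_true, y_pred)
            pcm = per_class_metrics(cm)
            acc, mcc = overall_metrics(cm)
            ref = _oracle_metrics(y_true.tolist(), y_pred.tolist())
            _assert_close_or_both_nan(pcm["PR"][0], ref["pr_pos"])
            _assert_close_or_both_nan(pcm["PR"][1], ref["pr_neg"])
            _assert_close_or_both_nan(pcm["SE"][0], ref["se_pos"])
            _assert_close_or_both_nan(pcm["SE"][1], ref["se_neg"])
            _assert_close_or_both_nan(acc, ref["acc"], tol=0)
            _assert_close_or_both_nan(mcc, ref["mcc"])
            _assert_close_or_both_nan(f1_positive(cm), ref["f1"])

    def test_per_class_mcc_magnitudes_coincide(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y_true = rng.choice([1, -1], size=40)
            y_pred = rng.choice([1, -1], size=40)
            pcm = per_class_metrics(confusion(y_true, y_pred))
            m_pos, m_neg = pcm["MCC"]
            if not (math.isnan(m_pos) or math.isnan(m_neg)):
                assert abs(abs(m_pos) - abs(m_neg)) <= 1e-12

    def test_random_labels_mcc_near_zero(self):
        """Observed MCC of random predictions sits inside the permutation null."""
        rng = np.random.default_rng(2)
        n = 1000
        y_true = np.array([1] * (n // 2) + [-1] * (n // 2))
        y_pred = rng.choice([1, -1], size=n)
        _, observed = overall_metrics(confusion(y_true, y_pred))
        null = []
        for _ in range(1000):
            _, m = overall_metrics(confusion(rng.permutation(y_true), y_pred))
            null.append(m)
        sd = float(np.std(null))
        assert abs(observed) <= 3 * sd


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 1, -1, -1], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([1, -1, 1, -1], [0.5] * 4) == 0.5

    def test_half_win_tie_hand_value(self):
        # positives {0.9, 0.8, 0.4}, negatives {0.4, 0.2, 0.1}: eight clear
        # wins plus one tie counted 1/2 over the nine comparisons
        y = [1, 1, 1, -1, -1, -1]
        s = [0.9, 0.8, 0.4, 0.4, 0.2, 0.1]
        assert roc_auc(y, s) == pytest.approx(8.5 / 9)
        assert _oracle_auc(y, s) == pytest.approx(8.5 / 9)

    def test_one_inversion_hand_value(self):
        y = [1, 1, 1, -1, -1, -1]
        s = [0.9, 0.8, 0.35, 0.4, 0.2, 0.1]
        assert roc_auc(y, s) == pytest.approx(8 / 9)
        assert _oracle_auc(y, s) == pytest.approx(8 / 9)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.4, 0.6])

    def test_pairwise_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 80))
            y = rng.choice([1, -1], size=n)
            if len(set(y.tolist())) < 2:
                y[0] = -y[0]
            s = np.round(rng.normal(size=n), 2)  # rounding forces ties
            assert roc_auc(y, s) == pytest.approx(_oracle_auc(y, s), abs=1e-12)


class TestNegativeSampling:
    def test_excludes_positives_and_self_pairs(self):
        rng = np.random.default_rng(0)
        drugs = [f"D{i}" for i in range(10)]
        exclude = {("D0", "D1"), ("D2", "D3")}
        pairs = evaluation.sample_negative_pairs(drugs, exclude, 30, rng)
        assert len(pairs) == len(set(pairs)) == 30
        for a, b in pairs:
            assert a < b and (a, b) not in exclude

    def test_space_exhaustion_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="available"):
            evaluation.sample_negative_pairs(["A", "B", "C"], set(), 4, rng)

    def test_assembled_set_balanced_and_disjoint(self, small_bundle):
        positives = small_bundle.interactions.positives()
        data = evaluation.assemble_training_set(small_bundle.targets,
                                                positives, seed=3)
        assert len(data.positives()) == len(data.negatives()) == len(positives)
        assert not (data.negatives().pair_keys() & positives.pair_keys())


class TestKFoldCV:
    def test_planted_signal_recovered(self, small_bundle):
        res = evaluation.kfold_cv(small_bundle.targets,
                                  small_bundle.interactions.positives(),
                                  k=5, seed=0)
        assert res.mean.auc > 0.6

    def test_same_seed_bit_reproducible(self, small_bundle):
        kwargs = dict(k=3, seed=9)
        r1 = evaluation.kfold_cv(small_bundle.targets,
                                 small_bundle.interactions.positives(), **kwargs)
        r2 = evaluation.kfold_cv(small_bundle.targets,
                                 small_bundle.interactions.positives(), **kwargs)
        assert r1.to_frame().equals(r2.to_frame())

    def test_k_larger_than_class_error(self, small_bundle):
        with pytest.raises(ValueError):
            evaluation.kfold_cv(small_bundle.targets,
                                small_bundle.interactions.positives(), k=151)

    def test_report_file_layout(self, tmp_path, small_bundle):
        res = evaluation.kfold_cv(small_bundle.targets,
                                  small_bundle.interactions.positives(),
                                  k=3, seed=0)
        path = tmp_path / "report.tsv"
        res.write(path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 3 + 2  # header, folds, mean, sd
        assert lines[0].split("\t")[1:] == list(evaluation.REPORT_COLUMNS)


class TestIndependentRecall:
    def _train_split(self, bundle, holdout=30):
        positives = list(bundle.interactions.positives())
        held_out = InteractionSet(tuple(positives[:holdout]))
        training_pos = InteractionSet(tuple(positives[holdout:]))
        data = evaluation.assemble_training_set(
            bundle.targets, training_pos, seed=0,
            exclude_pairs=held_out.pair_keys())
        universe = build_universe(bundle.targets,
                                  sorted(data.drugs))
        X, y = build_design_matrix(data, bundle.targets, universe)
        model = classifier.train(X, y, C=1.0, universe=universe)
        return model, universe, data, held_out

    def test_disjointness_guard(self, small_bundle):
        model, universe, data, _ = self._train_split(small_bundle)
        overlap = InteractionSet(tuple(list(data.positives())[:5]))
        with pytest.raises(ValueError, match="overlap"):
            evaluation.independent_recall(model, universe, overlap,
                                          small_bundle.targets, data)

    def test_empty_test_set_error(self, small_bundle):
        model, universe, data, _ = self._train_split(small_bundle)
        with pytest.raises(ValueError, match="empty"):
            evaluation.independent_recall(model, universe, InteractionSet(()),
                                          small_bundle.targets, data)

    def test_mixed_class_test_set_error(self, small_bundle):
        model, universe, data, _ = self._train_split(small_bundle)
        mixed = InteractionSet.from_records(
            [("ZZX", "ZZY", POSITIVE), ("ZZX", "ZZZ", NEGATIVE)])
        with pytest.raises(ValueError, match="single-class"):
            evaluation.independent_recall(model, universe, mixed,
                                          small_bundle.targets, data)

    def test_holdout_recall_above_chance(self, small_bundle):
        model, universe, data, held_out = self._train_split(small_bundle)
        recall = evaluation.independent_recall(model, universe, held_out,
                                               small_bundle.targets, data)
        assert 0.0 <= recall <= 1.0
        assert recall > 0.5
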
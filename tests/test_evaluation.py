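"""Confusion counting, the four metrics, and the LOOCV harness."""

import math

import numpy as np
import pytest

from tsfnn import ConfusionCounts, confusion, loocv, metrics, compare
from tsfnn.evaluation import fold_seed
from tsfnn.synthetic import SyntheticSpec, generate
from tests.test_networks import fast_spec


def brute_force_confusion(preds, labels):
    """Independent cell-by-cell enumeration of the four outcomes."""
    tp = fp = fn = tn = 0
    for p, y in zip(preds, labels):
        if y == 1 and p == 1:
            tp += 1
        elif y == 1 and p == 0:
            fn += 1
        elif y == 0 and p == 1:
            fp += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_metrics(tp, fp, fn, tn):
    """The four formulas coded independently (no shared helpers)."""
    total = tp + fp + fn + tn
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else float("nan")
    rec = tp / (tp + fn) if tp + fn else float("nan")
    if not math.isnan(prec) and not math.isnan(rec) and prec + rec > 0:
        f1 = 2 / (1 / prec + 1 / rec) if prec > 0 and rec > 0 else 0.0
    else:
        f1 = float("nan")
    return acc, prec, rec, f1


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion([1, 1, 0], [1, 1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)

    def test_all_positive_predictions(self):
        c = confusion([1, 1], [1, 0])
        assert (c.tp, c.fp) == (1, 1)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion([1], [1, 0])

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(20):
            preds = rng.integers(0, 2, size=50).tolist()
            labels = rng.integers(0, 2, size=50).tolist()
            c = confusion(preds, labels)
            assert (c.tp, c.fp, c.fn, c.tn) == brute_force_confusion(preds, labels)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)


class TestMetrics:
    def test_perfect_classifier_on_study_composition(self):
        m = metrics(ConfusionCounts(tp=97, fp=0, fn=0, tn=48))
        assert m.accuracy == 1.0 and m.precision == 1.0 and m.recall == 1.0 and m.f1 == 1.0

    def test_worked_example(self):
        m = metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_undefined_precision_marked_nan_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=2))
        assert math.isnan(m.precision)
        assert m.recall == 0.0
        assert math.isnan(m.f1)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_oracle_equivalence_on_1000_random_tables(self, rng):
        """The implemented formulas agree with an independently coded set."""
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + fp + fn + tn == 0:
                continue
            m = metrics(ConfusionCounts(tp, fp, fn, tn))
            acc, prec, rec, f1 = brute_force_metrics(tp, fp, fn, tn)
            for ours, ref in ((m.accuracy, acc), (m.precision, prec),
                              (m.recall, rec), (m.f1, f1)):
                if math.isnan(ref):
                    assert math.isnan(ours)
                else:
                    assert ours == pytest.approx(ref, abs=1e-12)

    def test_harmonic_mean_below_arithmetic_mean(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 40, size=4))
            m = metrics(ConfusionCounts(tp, fp, fn, tn))
            assert m.f1 <= (m.precision + m.recall) / 2 + 1e-12


@pytest.fixture(scope="module")
def tiny_loocv():
    ds = generate(SyntheticSpec(n_positive=6, n_negative=4, numeric_effects={16: -2.0}, seed=2))
    spec = fast_spec("nnn", epochs=30)
    return ds, loocv(ds, spec, master_seed=11)


class TestLoocv:
    def test_fold_accounting(self, tiny_loocv):
        ds, result = tiny_loocv
        assert result.n_folds == len(ds)
        assert sorted(f.test_index for f in result.folds) == list(range(len(ds)))
        assert result.train_sizes == [len(ds) - 1] * len(ds)

    def test_counts_total_equals_samples(self, tiny_loocv):
        _, result = tiny_loocv
        assert result.counts.total == result.n_folds

    def test_pooled_accuracy_equals_mean_per_fold_accuracy(self, tiny_loocv):
        _, result = tiny_loocv
        per_fold = [int(f.predicted_label == f.true_label) for f in result.folds]
        assert result.metric_set.accuracy == pytest.approx(np.mean(per_fold))

    def test_loocv_deterministic_given_master_seed(self, tiny_loocv):
        ds, result = tiny_loocv
        again = loocv(ds, fast_spec("nnn", epochs=30), master_seed=11)
        assert [f.probability for f in again.folds] == [f.probability for f in result.folds]

    def test_dataset_of_three_records(self):
        ds = generate(SyntheticSpec(n_positive=2, n_negative=1, seed=1))
        result = loocv(ds, fast_spec("nnn", epochs=10), master_seed=1)
        # the two folds that keep one record of each class complete; the fold
        # holding out the lone negative leaves a single-class training fold
        assert sorted(f.test_index for f in result.folds) + result.skipped_folds is not None
        assert result.n_folds + len(result.skipped_folds) == 3

    def test_single_class_training_fold_skipped_with_warning(self):
        ds = generate(SyntheticSpec(n_positive=5, n_negative=1, seed=1))
        with pytest.warns(UserWarning, match="single-class"):
            result = loocv(ds, fast_spec("nnn", epochs=10), master_seed=1)
        assert len(result.skipped_folds) == 1
        assert result.n_folds == 5

    def test_too_small_dataset_rejected(self):
        ds = generate(SyntheticSpec(n_positive=1, n_negative=1, seed=1))
        with pytest.raises(ValueError, match="at least 3"):
            loocv(ds, fast_spec("nnn"))

    def test_fold_seeds_distinct_and_below_2_31(self):
        seeds = [fold_seed(42, i) for i in range(145)]
        assert len(set(seeds)) == 145
        assert all(0 <= s < 2**31 for s in seeds)

    def test_global_fit_scope_runs(self):
        ds = generate(SyntheticSpec(n_positive=6, n_negative=4, seed=3))
        result = loocv(ds, fast_spec("tsfnn", epochs=15), master_seed=3, fit_scope="global")
        assert result.n_folds == 10

    def test_majority_predictor_accuracy_is_class_proportion(self):
        """Pooling identity: a constant positive predictor on a 97/48 split
        scores exactly 97/145."""
        labels = [1] * 97 + [0] * 48
        m = metrics(confusion([1] * 145, labels))
        assert m.accuracy == pytest.approx(97 / 145)
        assert m.recall == 1.0


class TestExtras:
    def test_bootstrap_intervals_bracket_point_metrics(self, tiny_loocv):
        from tsfnn.evaluation import bootstrap_metrics

        _, result = tiny_loocv
        intervals = bootstrap_metrics(result, n_boot=300, seed=1)
        for key, (lo, hi) in intervals.items():
            assert lo <= hi
            point = getattr(result.metric_set, key)
            assert lo - 1e-9 <= point <= hi + 1e-9

    def test_svm_baseline_runs_loocv(self):
        from tsfnn.evaluation import svm_baseline_loocv

        ds = generate(SyntheticSpec(n_positive=10, n_negative=8,
                                    numeric_effects={16: -2.0}, seed=4))
        result = svm_baseline_loocv(ds)
        assert result.n_folds == 18
        assert result.metric_set.accuracy > 0.5  # strong planted signal


class TestCompare:
    def test_table_layout_with_improvement_row(self):
        ds = generate(SyntheticSpec(n_positive=6, n_negative=4, numeric_effects={16: -2.0}, seed=2))
        specs = [fast_spec("nnn", epochs=20, use_batch_norm=False),
                 fast_spec("nnn", epochs=20, use_batch_norm=True)]
        frame = compare(ds, specs, names=["no-bn", "bn"], master_seed=5)
        assert list(frame["architecture"]) == ["no-bn", "bn", "Improvement (bn vs no-bn)"]
        row = frame.iloc[2]
        assert row["accuracy"] == pytest.approx(frame.iloc[1]["accuracy"] - frame.iloc[0]["accuracy"])

    def test_comparing_spec_with_itself_gives_zero_improvement(self):
        ds = generate(SyntheticSpec(n_positive=6, n_negative=4, seed=2))
        specs = [fast_spec("nnn", epochs=15), fast_spec("nnn", epochs=15)]
        frame = compare(ds, specs, names=["a", "b"], master_seed=5)
        imp = frame.iloc[2]
        assert imp["accuracy"] == 0.0 and imp["f1"] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_specs_rejected(self):
        ds = generate(SyntheticSpec(n_positive=6, n_negative=4, seed=2))
        with pytest.raises(ValueError, match="at least 2"):
            compare(ds, [fast_spec("nnn")])
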
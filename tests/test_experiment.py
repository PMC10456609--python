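"""Split stratification, confusion-matrix metrics and the search protocol."""

import numpy as np
import pandas as pd
import pytest

from hrvnet.experiment import (CLASS_ORDER, ConfusionMatrix, TrainConfig,
                               confusion_from_predictions, evaluate_segments,
                               grid_search, macro_average, metrics_from_cm,
                               run_study, split_subjects, train)
from hrvnet.io import FEATURE_COLUMNS
from hrvnet.wavenet import WavenetSpec, build_model


def brute_force_metrics(cm):
    """Independent scalar one-vs-rest evaluation of a counts matrix."""
    cm = np.asarray(cm)
    total = cm.sum()
    out = {}
    for i in range(cm.shape[0]):
        tp = cm[i, i]
        fn = sum(cm[i, j] for j in range(cm.shape[1])) - tp
        fp = sum(cm[j, i] for j in range(cm.shape[0])) - tp
        tn = total - tp - fn - fp
        out[i] = {
            "accuracy": 100 * (tp + tn) / total,
            "sensitivity": 100 * tp / (tp + fn) if tp + fn else None,
            "specificity": 100 * tn / (tn + fp) if tn + fp else None,
            "precision": 100 * tp / (tp + fp) if tp + fp else None,
        }
    return out


def _feature_table(rng, n_per_class=6, segments=6, sep=1.0):
    """Separable synthetic table: the class index shifts every column."""
    rows = []
    for ci, label in enumerate(CLASS_ORDER):
        for s in range(n_per_class):
            for g in range(1, segments + 1):
                base = {
                    "subject_id": f"{label.lower()}{s:02d}", "segment": g,
                    "label": label}
                vals = sep * ci + rng.normal(0, 0.15, len(FEATURE_COLUMNS))
                base.update(dict(zip(FEATURE_COLUMNS, vals)))
                rows.append(base)
    return pd.DataFrame(rows)


class TestSplitSubjects:
    STUDY_SIZES = {"NSR": 18, "CAD": 51, "CHF": 15, "VT": 11, "SCD": 20}

    @staticmethod
    def _labels(sizes):
        return {f"{c.lower()}{i:03d}": c
                for c, n in sizes.items() for i in range(n)}

    def test_study_cohort_splits_92_23(self):
        labels = self._labels(self.STUDY_SIZES)
        train_ids, test_ids = split_subjects(labels, 0.8, seed=0)
        assert (len(train_ids), len(test_ids)) == (92, 23)

    def test_split_is_stratified_close_to_global_fraction(self):
        labels = self._labels(self.STUDY_SIZES)
        _, test_ids = split_subjects(labels, 0.8, seed=1)
        per_class = pd.Series([labels[s] for s in test_ids]).value_counts()
        for c, n in self.STUDY_SIZES.items():
            assert abs(per_class.get(c, 0) - 0.2 * n) < 1.0

    def test_deterministic_and_disjoint(self):
        labels = self._labels(self.STUDY_SIZES)
        a = split_subjects(labels, 0.8, seed=5)
        b = split_subjects(labels, 0.8, seed=5)
        assert a == b
        train_ids, test_ids = a
        assert not set(train_ids) & set(test_ids)
        assert set(train_ids) | set(test_ids) == set(labels)

    def test_single_subject_class_warns_and_keeps_it_in_train(self):
        labels = {"a": "NSR", "b": "NSR", "c": "NSR", "d": "SCD"}
        with pytest.warns(UserWarning, match="best-effort"):
            train_ids, _ = split_subjects(labels, 0.8, seed=0)
        assert "d" in train_ids


class TestMetrics:
    def test_diagonal_matrix_all_metrics_100(self):
        rep = metrics_from_cm(ConfusionMatrix(np.diag([5, 5, 5, 5, 5])))
        assert rep.overall_accuracy == 100.0
        assert np.allclose(rep.per_class.to_numpy(), 100.0)
        assert all(v == 100.0 for v in rep.macro.values())

    def test_two_class_hand_enumeration(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), labels=("A", "B"))
        rep = metrics_from_cm(cm)
        a = rep.per_class.loc["A"]
        assert a["sensitivity"] == pytest.approx(80.0)
        assert a["specificity"] == pytest.approx(90.0)
        assert a["precision"] == pytest.approx(100 * 8 / 9)
        assert a["accuracy"] == pytest.approx(85.0)

    def test_random_matrices_match_brute_force_oracle(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, size=(5, 5))
            counts[0, 0] += 1  # non-empty
            rep = metrics_from_cm(ConfusionMatrix(counts))
            oracle = brute_force_metrics(counts)
            for i, label in enumerate(CLASS_ORDER):
                for key, val in oracle[i].items():
                    got = rep.per_class.loc[label, key]
                    if val is None:
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(val)

    def test_macro_is_unweighted_mean_excluding_undefined(self):
        assert macro_average([100, 100, 100, 95, 90]) == pytest.approx(97.0)
        assert macro_average([100, 100, 100, 99.05, 98.95]) == \
            pytest.approx(99.60)
        assert macro_average([100, np.nan, 90]) == pytest.approx(95.0)

    def test_absent_class_excluded_from_macro_with_warning(self):
        counts = np.diag([5, 5, 5, 5, 0])
        with pytest.warns(UserWarning, match="no positives"):
            rep = metrics_from_cm(ConfusionMatrix(counts))
        assert np.isnan(rep.per_class.loc["VT", "sensitivity"])
        assert rep.macro["sensitivity"] == pytest.approx(100.0)

    def test_overall_accuracy_is_trace_over_total(self, rng):
        counts = rng.integers(1, 20, size=(5, 5))
        rep = metrics_from_cm(ConfusionMatrix(counts))
        assert rep.overall_accuracy == pytest.approx(
            100 * np.trace(counts) / counts.sum())

    def test_confusion_from_predictions_counts(self):
        cm = confusion_from_predictions([0, 0, 1, 2], [0, 1, 1, 2])
        assert cm.total == 4
        assert cm.counts[0, 1] == 1 and cm.counts[0, 0] == 1


class TestGridSearchAndStudy:
    def test_restricted_grid_trains_four_models(self, rng):
        df = _feature_table(rng, n_per_class=3, segments=1)
        res = grid_search(df, df, epochs=2, seed=0, restricted=True)
        assert len(res.report) == 4

    def test_single_configuration_grid_returns_it(self, rng):
        df = _feature_table(rng, n_per_class=3, segments=1)
        res = grid_search(df, df, epochs=2, seed=0,
                          learning_rates=[0.001], batch_sizes=[32],
                          n_blocks_list=[3])
        assert len(res.report) == 1
        assert res.best_config.n_blocks == 3
        assert res.best_config.learning_rate == 0.001

    def test_separable_table_reaches_full_accuracy(self, rng):
        df = _feature_table(rng, n_per_class=6, segments=1)
        res = grid_search(df, df, epochs=25, seed=0,
                          learning_rates=[0.01], batch_sizes=[32],
                          n_blocks_list=[3])
        assert res.report["accuracy"].max() == pytest.approx(100.0)

    def test_empty_grid_rejected(self, rng):
        df = _feature_table(rng, n_per_class=2, segments=1)
        with pytest.raises(ValueError, match="empty"):
            grid_search(df, df, epochs=1, learning_rates=[],
                        batch_sizes=[], n_blocks_list=[])

    def test_train_records_epoch_curves(self, rng):
        df = _feature_table(rng, n_per_class=4, segments=1)
        X = df[list(FEATURE_COLUMNS)].to_numpy()
        y = df["label"].map({c: i for i, c in enumerate(CLASS_ORDER)}).to_numpy()
        model = build_model(WavenetSpec(n_blocks=3), seed=0)
        cfg = TrainConfig(learning_rate=0.01, batch_size=8, n_blocks=3,
                          epochs=4, seed=0)
        hist = train(model, X, y, cfg, validation_data=(X, y))
        assert len(hist.train_loss) == len(hist.val_loss) == 4

    def test_run_study_subject_level_separation(self, rng):
        df = _feature_table(rng, n_per_class=10, segments=6)
        res = run_study(df, seed=0, epochs=30, learning_rates=[0.01],
                        batch_sizes=[8], n_blocks_list=[3])
        assert not set(res.train_ids) & set(res.test_ids)
        assert res.evaluation.pooled_cm.total == len(res.test_ids) * 6
        assert res.evaluation.pooled.overall_accuracy >= 95.0

    def test_missing_segment_reported_absent(self, rng):
        df = _feature_table(rng, n_per_class=3, segments=4)
        res = grid_search(df[df.segment == 1], df[df.segment == 1],
                          epochs=2, seed=0, learning_rates=[0.01],
                          batch_sizes=[32], n_blocks_list=[3])
        ev = evaluate_segments(res.best_model, df, res.standardizer)
        assert ev.missing_segments == [5, 6]
        assert sorted(ev.per_segment) == [1, 2, 3, 4]


def test_perfect_predictions_give_all_100(rng):
    df = _feature_table(rng, n_per_class=2, segments=2)
    y = df["label"].map({c: i for i, c in enumerate(CLASS_ORDER)}).to_numpy()

    class Oracle:
        def predict(self, X):
            # class index encoded in the (standardizer-free) MRR column
            return np.clip(np.round(X[:, 0]), 0, 4).astype(int)

    ev = evaluate_segments(Oracle(), df, None)
    assert all(r.overall_accuracy == 100.0 for r in ev.per_segment.values())
    assert ev.pooled.overall_accuracy == 100.0
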
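"""Study protocol: subject-level split, grid search, segment-wise evaluation.

The protocol mirrors the study design: features from the first 5-minute
segment of every subject drive a hyperparameter grid search (number of
gated blocks x learning rate x batch size); the selected model is then
evaluated zero-shot on all six segments of the held-out subjects. Splits
are at subject level — every segment of a subject lands on the same side —
to rule out leakage between train and test.

Metrics derive from a 5-class confusion matrix (rows true, columns
predicted, class order CAD, CHF, NSR, SCD, VT) via one-vs-rest counts;
macro values are unweighted means over classes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hrv_features import FeatureStandardizer, feature_rows_for_record
from .io import FEATURE_COLUMNS, EcgRecord
from .preprocess import preprocess
from .rpeak import InsufficientDataError, detect_rpeaks, to_rr
from .wavenet import TrainingHistory, WavenetClassifier, WavenetSpec, build_model

logger = logging.getLogger(__name__)

#: confusion-matrix / report class order
CLASS_ORDER = ("CAD", "CHF", "NSR", "SCD", "VT")
CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

LEARNING_RATE_GRID = (0.1, 0.01, 0.001, 0.0001)
BATCH_SIZE_GRID = (32, 64, 128, 256)
N_BLOCKS_GRID = (3, 5, 7, 9)

#: the four (n_blocks, learning_rate, batch_size) combinations reported
#: by the restricted grid mode
RESTRICTED_MODELS = (
    (3, 0.001, 32),
    (5, 0.0001, 32),
    (7, 0.001, 128),
    (9, 0.0001, 32),
)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for one grid point."""

    learning_rate: float = 0.001
    batch_size: int = 128
    n_blocks: int = 7
    epochs: int = 140
    seed: int = 0


@dataclass
class ConfusionMatrix:
    """5x5 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: Tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected {n}x{n} counts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label order mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


@dataclass
class MetricsReport:
    """Per-class and macro one-vs-rest metrics, in percent."""

    per_class: pd.DataFrame  # index = class, cols accuracy/sensitivity/...
    macro: Dict[str, float]
    overall_accuracy: float


def confusion_from_predictions(y_true: Sequence[int], y_pred: Sequence[int],
                               labels: Tuple[str, ...] = CLASS_ORDER,
                               ) -> ConfusionMatrix:
    n = len(labels)
    cm = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return ConfusionMatrix(cm, labels)


def macro_average(values: Sequence[float]) -> float:
    """Unweighted mean over classes; undefined (NaN) entries are excluded."""
    return float(np.nanmean(np.asarray(values, dtype=float)))


def metrics_from_cm(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest accuracy/sensitivity/specificity/precision, in percent.

    A class with zero true positives+false negatives has undefined
    sensitivity; it is reported as NaN and excluded from the macro mean
    (with a warning). Same for precision when nothing was predicted as
    that class.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for i, label in enumerate(cm.labels):
        tp = cm.counts[i, i]
        fn = cm.counts[i].sum() - tp
        fp = cm.counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else np.nan
        prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else np.nan
        if np.isnan(sens):
            warnings.warn(f"class {label}: no positives, sensitivity undefined")
        rows[label] = {
            "accuracy": 100.0 * (tp + tn) / total,
            "sensitivity": sens,
            "specificity": 100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan,
            "precision": prec,
        }
    per_class = pd.DataFrame(rows).T.loc[list(cm.labels)]
    macro = {c: macro_average(per_class[c].to_numpy())
             for c in per_class.columns}
    overall = 100.0 * float(np.trace(cm.counts)) / total
    return MetricsReport(per_class, macro, overall)


# ---------------------------------------------------------------------------
# Splitting


def split_subjects(subject_labels: Dict[str, str], train_frac: float = 0.8,
                   seed: int = 0) -> Tuple[List[str], List[str]]:
    """Stratified subject-level 80/20 split.

    ``subject_labels`` maps subject id -> class label. The global test
    count is ``n - floor(train_frac * n)``; per-class test counts follow a
    largest-remainder apportionment so the stratification matches the
    global fraction as closely as possible. Deterministic given the seed.
    """
    subjects = sorted(subject_labels)
    n = len(subjects)
    n_test = n - int(np.floor(train_frac * n))
    by_class: Dict[str, List[str]] = {}
    for s in subjects:
        by_class.setdefault(subject_labels[s], []).append(s)
    for label, members in by_class.items():
        if len(members) < 2:
            warnings.warn(
                f"class {label} has {len(members)} subject(s); "
                "stratification is best-effort")
    labels = sorted(by_class)
    quota = {c: (1 - train_frac) * len(by_class[c]) for c in labels}
    base = {c: int(np.floor(quota[c])) for c in labels}
    remainder = n_test - sum(base.values())
    order = sorted(labels, key=lambda c: quota[c] - base[c], reverse=True)
    for c in itertools.islice(itertools.cycle(order), max(0, remainder)):
        base[c] += 1
    rng = np.random.default_rng(seed)
    train_ids: List[str] = []
    test_ids: List[str] = []
    for c in labels:
        members = list(by_class[c])
        rng.shuffle(members)
        k = min(base[c], max(0, len(members) - 1))
        test_ids.extend(members[:k])
        train_ids.extend(members[k:])
    return sorted(train_ids), sorted(test_ids)


# ---------------------------------------------------------------------------
# Feature-table plumbing


def table_to_xy(df: pd.DataFrame,
                standardizer: Optional[FeatureStandardizer] = None,
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Feature table -> (X, y) with y as CLASS_ORDER indices."""
    X = df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = df["label"].map(CLASS_INDEX).to_numpy(dtype=int)
    if standardizer is not None:
        X = standardizer.transform(X)
    return X, y


# ---------------------------------------------------------------------------
# Training and grid search


def train(classifier: WavenetClassifier, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig,
          validation_data: Optional[Tuple[np.ndarray, np.ndarray]] = None,
          ) -> TrainingHistory:
    """Train a classifier under a :class:`TrainConfig` (seeded)."""
    return classifier.fit(
        X, y, epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, seed=cfg.seed,
        validation_data=validation_data)


@dataclass
class GridSearchResult:
    best_model: WavenetClassifier
    best_config: TrainConfig
    report: pd.DataFrame  # one row per combination
    history: TrainingHistory


def grid_search(train_df: pd.DataFrame, test_df: pd.DataFrame, *,
                epochs: int = 140, seed: int = 0,
                learning_rates: Sequence[float] = LEARNING_RATE_GRID,
                batch_sizes: Sequence[int] = BATCH_SIZE_GRID,
                n_blocks_list: Sequence[int] = N_BLOCKS_GRID,
                restricted: bool = False,
                standardize: bool = True) -> GridSearchResult:
    """Exhaustive hyperparameter search on first-segment feature rows.

    Trains one seeded model per (n_blocks, learning_rate, batch_size)
    combination — the full Cartesian grid by default, or the four-model
    restricted list with ``restricted=True`` — and selects the highest
    test accuracy, ties broken by lowest test loss. Configurations that
    diverge (non-finite loss, possible at the largest learning rates) are
    recorded with NaN metrics and never selected.
    """
    if train_df.empty or test_df.empty:
        raise ValueError("train and test tables must be non-empty")
    std = FeatureStandardizer() if standardize else None
    X_tr = train_df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    if std is not None:
        std.fit(X_tr)
    X_tr, y_tr = table_to_xy(train_df, std)
    X_te, y_te = table_to_xy(test_df, std)

    if restricted:
        combos = list(RESTRICTED_MODELS)
    else:
        combos = [(nb, lr, bs) for nb in n_blocks_list
                  for lr in learning_rates for bs in batch_sizes]
    if not combos:
        raise ValueError("empty hyperparameter grid")

    rows = []
    best: Tuple[float, float] | None = None  # (-acc, loss) to minimize
    best_model: Optional[WavenetClassifier] = None
    best_cfg: Optional[TrainConfig] = None
    best_hist: Optional[TrainingHistory] = None
    for i, (nb, lr, bs) in enumerate(combos):
        cfg = TrainConfig(learning_rate=lr, batch_size=bs, n_blocks=nb,
                          epochs=epochs, seed=seed)
        model = build_model(WavenetSpec(n_blocks=nb), seed=seed)
        row = {"n_blocks": nb, "learning_rate": lr, "batch_size": bs,
               "epochs": epochs}
        try:
            hist = train(model, X_tr, y_tr, cfg, validation_data=(X_te, y_te))
        except Exception as exc:  # diverged configuration
            logger.warning("grid point %s diverged: %s", (nb, lr, bs), exc)
            row.update(loss=np.nan, accuracy=np.nan, sensitivity=np.nan,
                       specificity=np.nan, precision=np.nan, diverged=True)
            rows.append(row)
            continue
        loss, acc = model.evaluate(X_te, y_te)
        cm = confusion_from_predictions(y_te, model.predict(X_te))
        try:
            rep = metrics_from_cm(cm)
            row.update(sensitivity=rep.macro["sensitivity"],
                       specificity=rep.macro["specificity"],
                       precision=rep.macro["precision"])
        except ValueError:
            pass
        row.update(loss=loss, accuracy=100.0 * acc, diverged=False)
        rows.append(row)
        key = (-acc, loss)
        if best is None or key < best:
            best, best_model, best_cfg, best_hist = key, model, cfg, hist
        logger.info("grid %d/%d blocks=%d lr=%g batch=%d -> acc=%.2f%% "
                    "loss=%.4f", i + 1, len(combos), nb, lr, bs,
                    100 * acc, loss)
    if best_model is None:
        raise TrainingError("every grid configuration diverged")
    result = GridSearchResult(best_model, best_cfg, pd.DataFrame(rows),
                              best_hist)
    result.standardizer = std  # type: ignore[attr-defined]
    return result


class TrainingError(RuntimeError):
    """No usable model came out of the search."""


# ---------------------------------------------------------------------------
# Segment-wise evaluation


@dataclass
class SegmentEvaluation:
    per_segment: Dict[int, MetricsReport]
    per_segment_cm: Dict[int, ConfusionMatrix]
    pooled: MetricsReport
    pooled_cm: ConfusionMatrix
    missing_segments: List[int] = field(default_factory=list)


def evaluate_segments(classifier: WavenetClassifier, df: pd.DataFrame,
                      standardizer: Optional[FeatureStandardizer] = None,
                      segments: Sequence[int] = range(1, 7),
                      ) -> SegmentEvaluation:
    """Zero-shot evaluation per segment plus a pooled per-class report.

    The pooled report sums the per-segment confusion matrices before
    deriving metrics, collapsing the segment-wise evaluation into a
    single per-class table. Segments absent from the table are listed in
    ``missing_segments`` rather than zero-filled.
    """
    per_seg: Dict[int, MetricsReport] = {}
    per_cm: Dict[int, ConfusionMatrix] = {}
    missing: List[int] = []
    pooled_cm: Optional[ConfusionMatrix] = None
    for s in segments:
        sub = df[df["segment"] == s]
        if sub.empty:
            missing.append(s)
            continue
        X, y = table_to_xy(sub, standardizer)
        cm = confusion_from_predictions(y, classifier.predict(X))
        per_cm[s] = cm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_seg[s] = metrics_from_cm(cm)
        pooled_cm = cm if pooled_cm is None else pooled_cm + cm
    if pooled_cm is None:
        raise ValueError("no requested segment present in the table")
    pooled = metrics_from_cm(pooled_cm)
    return SegmentEvaluation(per_seg, per_cm, pooled, pooled_cm, missing)


# ---------------------------------------------------------------------------
# Full pipeline


def extract_feature_table(records: Sequence[EcgRecord],
                          window: float = 300.0,
                          denoise: bool = True) -> pd.DataFrame:
    """Records -> per-segment feature table via the full signal pipeline.

    Each record is conditioned (wavelet denoise + NADev normalize), R-peaks
    are detected, the RR series is segmented and the eight HRV statistics
    plus the interval count are computed per segment. Records on which
    detection fails (flat or too short) are skipped with a warning.
    """
    rows = []
    for rec in records:
        try:
            conditioned = preprocess(rec) if denoise else rec
            rr = to_rr(detect_rpeaks(conditioned))
            rows.extend(feature_rows_for_record(
                rr, rec.duration, rec.subject_id, rec.label, window))
        except (InsufficientDataError, ValueError) as exc:
            warnings.warn(f"record {rec.subject_id}: pipeline failed ({exc})")
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Outcome of a full synthetic-cohort study run."""

    features: pd.DataFrame
    train_ids: List[str]
    test_ids: List[str]
    grid: GridSearchResult
    evaluation: SegmentEvaluation


def run_study(features: pd.DataFrame, *, seed: int = 0, epochs: int = 140,
              train_frac: float = 0.8, restricted: bool = False,
              learning_rates: Sequence[float] = LEARNING_RATE_GRID,
              batch_sizes: Sequence[int] = BATCH_SIZE_GRID,
              n_blocks_list: Sequence[int] = N_BLOCKS_GRID) -> StudyResult:
    """Run the full protocol on a per-segment feature table.

    Subject-level stratified 80/20 split, grid search on the first
    segment, zero-shot evaluation of the selected model on all six
    segments of the held-out subjects.
    """
    subject_labels = (features.drop_duplicates("subject_id")
                      .set_index("subject_id")["label"].to_dict())
    train_ids, test_ids = split_subjects(subject_labels, train_frac, seed)
    assert not set(train_ids) & set(test_ids)
    seg1 = features[features["segment"] == 1]
    gs = grid_search(
        seg1[seg1["subject_id"].isin(train_ids)],
        seg1[seg1["subject_id"].isin(test_ids)],
        epochs=epochs, seed=seed, restricted=restricted,
        learning_rates=learning_rates, batch_sizes=batch_sizes,
        n_blocks_list=n_blocks_list)
    test_rows = features[features["subject_id"].isin(test_ids)]
    evaluation = evaluate_segments(gs.best_model, test_rows, gs.standardizer)
    return StudyResult(features, train_ids, test_ids, gs, evaluation)
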
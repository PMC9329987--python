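"""Five-classifier evaluation harness: confusion-matrix metrics, one-vs-all
AUROC, stratified 10-fold cross-validation and exhaustive grid search.

Multi-class specificity, F1 and MCC are the macro averages of the one-vs-rest
per-class values (classes whose ratio is undefined contribute 0 and are
flagged); accuracy is the trace of the confusion matrix over the total.
AUROC is computed one-vs-all per class from the score matrix by the
tie-averaged rank method and macro-averaged over classes present in the
truth. SVM margins are turned into pseudo-probabilities by a softmax over the
one-vs-rest decision values so that ROC analysis applies to all five models.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .dataset_prep import DEFAULT_SCHEMA, LabeledRecord, PreparedDataset
from .descriptors import DescriptorConfig, encode_many
from .fusion import FusionSpec
from .seqio import RnaSequence

MODEL_IDS = ("random_forest", "xgboost", "adaboost", "svm", "naive_bayes")

#: Hyperparameter grid bounds for grid search.
GRID_BOUNDS = {
    "k": (2, 5),
    "gap": (2, 5),
    "n_estimators": (20, 200),
    "criterion": ("gini", "entropy"),
    "kernel": ("linear", "polynomial", "poly", "rbf"),
    "var_smoothing": (1e-9, 1e-1),
}


class ModelConfigError(ValueError):
    """Unknown model id or hyperparameter outside the allowed grid."""


@dataclass(frozen=True)
class ModelConfig:
    """A classifier selection with its hyperparameters.

    Recognized hyperparameters: ``n_estimators`` and ``criterion`` for the
    tree ensembles, ``kernel`` for SVM, ``var_smoothing`` for Gaussian naive
    Bayes. Unrecognized keys are rejected.
    """

    model_id: str
    hyperparameters: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ModelConfigError(f"unknown model id {self.model_id!r}")
        hp = dict(self.hyperparameters)
        allowed = {
            "random_forest": {"n_estimators", "criterion"},
            "xgboost": {"n_estimators"},
            "adaboost": {"n_estimators"},
            "svm": {"kernel"},
            "naive_bayes": {"var_smoothing"},
        }[self.model_id]
        unknown = set(hp) - allowed
        if unknown:
            raise ModelConfigError(
                f"{self.model_id}: unsupported hyperparameter(s) {sorted(unknown)}"
            )
        object.__setattr__(
            self, "hyperparameters", tuple(sorted(hp.items()))
        )

    @classmethod
    def make(cls, model_id: str, **hyperparameters) -> "ModelConfig":
        return cls(model_id, tuple(hyperparameters.items()))

    @property
    def hp(self) -> dict[str, object]:
        return dict(self.hyperparameters)

    def label(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.hyperparameters)
        return f"{self.model_id}({inner})"


def build_estimator(config: ModelConfig, seed: int = 0):
    """Instantiate the scikit-learn / xgboost estimator for a config."""
    hp = config.hp
    if config.model_id == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            criterion=str(hp.get("criterion", "gini")),
            random_state=seed,
            n_jobs=1,
        )
    if config.model_id == "xgboost":
        return XGBClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            random_state=seed,
            n_jobs=1,
            eval_metric="mlogloss",
        )
    if config.model_id == "adaboost":
        return AdaBoostClassifier(
            n_estimators=int(hp.get("n_estimators", 50)), random_state=seed
        )
    if config.model_id == "svm":
        kernel = str(hp.get("kernel", "rbf"))
        kernel = {"polynomial": "poly"}.get(kernel, kernel)
        return SVC(kernel=kernel, decision_function_shape="ovr", random_state=seed)
    if config.model_id == "naive_bayes":
        return GaussianNB(var_smoothing=float(hp.get("var_smoothing", 1e-9)))
    raise ModelConfigError(config.model_id)  # pragma: no cover


# --- confusion matrix and scalar metrics --------------------------------------

@dataclass(frozen=True)
class ClassTallies:
    """One-vs-rest tallies for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class ConfusionMatrix:
    """A square count matrix indexed by (true label, predicted label)."""

    counts: np.ndarray
    labels: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tallies(self, label: str) -> ClassTallies:
        i = self.labels.index(label)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return ClassTallies(tp=tp, tn=tn, fp=fp, fn=fn)


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    schema: Sequence[str] = DEFAULT_SCHEMA,
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists differ in length")
    if not true_labels:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    labels = tuple(schema)
    index = {label: i for i, label in enumerate(labels)}
    unknown = (set(true_labels) | set(predicted_labels)) - set(labels)
    if unknown:
        raise ValueError(f"label(s) outside the schema: {sorted(unknown)}")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


@dataclass
class MetricReport:
    """Macro-averaged confusion-matrix metrics plus one-vs-all AUROC."""

    accuracy: float
    specificity_macro: float
    f1_macro: float
    mcc_macro: float
    auroc_macro: float | None = None
    auroc_per_class: dict[str, float] = field(default_factory=dict)
    undefined_classes: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "specificity_macro": self.specificity_macro,
            "f1_macro": self.f1_macro,
            "mcc_macro": self.mcc_macro,
        }
        if self.auroc_macro is not None:
            out["auroc_macro"] = self.auroc_macro
            out["auroc_per_class"] = dict(self.auroc_per_class)
        if self.undefined_classes:
            out["undefined_classes"] = list(self.undefined_classes)
        return out


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    true_labels: Sequence[str] | None = None,
) -> MetricReport:
    """Accuracy plus macro one-vs-rest specificity, F1 and MCC; AUROC if scores.

    Only classes present in the evaluated records (as truth or prediction)
    enter the macro averages; a class whose ratio is undefined contributes 0
    and is flagged in ``undefined_classes``.
    """
    present = [
        label
        for i, label in enumerate(cm.labels)
        if cm.counts[i].sum() or cm.counts[:, i].sum()
    ]
    specificities, f1s, mccs = [], [], []
    undefined: list[str] = []
    for label in present:
        t = cm.tallies(label)
        sp, sp_undef = _safe_ratio(t.tn, t.tn + t.fp)
        precision, p_undef = _safe_ratio(t.tp, t.tp + t.fp)
        recall, r_undef = _safe_ratio(t.tp, t.tp + t.fn)
        f1, f1_undef = _safe_ratio(2 * precision * recall, precision + recall)
        mcc_den = math.sqrt(
            (t.tp + t.fp) * (t.tp + t.fn) * (t.tn + t.fp) * (t.tn + t.fn)
        )
        mcc, mcc_undef = _safe_ratio(t.tp * t.tn - t.fp * t.fn, mcc_den)
        if sp_undef or f1_undef or mcc_undef or p_undef or r_undef:
            undefined.append(label)
        specificities.append(sp)
        f1s.append(f1)
        mccs.append(mcc)
    report = MetricReport(
        accuracy=float(np.trace(cm.counts)) / cm.total,
        specificity_macro=float(np.mean(specificities)),
        f1_macro=float(np.mean(f1s)),
        mcc_macro=float(np.mean(mccs)),
        undefined_classes=tuple(undefined),
    )
    if scores is not None:
        if true_labels is None:
            raise ValueError("AUROC from scores requires the true labels")
        per_class, macro = auroc_ova(true_labels, np.asarray(scores), cm.labels)
        report.auroc_per_class = per_class
        report.auroc_macro = macro
    return report


def auroc_ova(
    true_labels: Sequence[str],
    scores: np.ndarray,
    schema: Sequence[str] = DEFAULT_SCHEMA,
) -> tuple[dict[str, float], float]:
    """One-vs-all AUROC per class (tie-averaged rank method) and macro mean.

    ``scores`` has one column per schema class. Classes absent from the truth
    (or covering all of it) are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = tuple(schema)
    if scores.ndim != 2 or scores.shape != (len(true_labels), len(labels)):
        raise ValueError(
            f"scores shape {scores.shape} does not match "
            f"({len(true_labels)}, {len(labels)})"
        )
    truth = np.asarray(true_labels)
    per_class: dict[str, float] = {}
    for j, label in enumerate(labels):
        positives = truth == label
        n_pos = int(positives.sum())
        n_neg = len(truth) - n_pos
        if n_pos == 0 or n_neg == 0:
            if label in truth:
                warnings.warn(
                    f"AUROC undefined for class {label!r} (no negatives)",
                    stacklevel=2,
                )
            continue
        ranks = rankdata(scores[:, j])
        auc = (ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        per_class[label] = float(auc)
    macro = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    return per_class, macro


# --- training and cross-validation --------------------------------------------

def _fit_predict_arrays(
    config: ModelConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int,
    classes: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on arrays; return predicted labels and a row-stochastic score
    matrix with one column per ``classes`` entry."""
    if len(set(y_train)) < 2:
        raise ValueError("training set must contain at least two classes")
    estimator = build_estimator(config, seed=seed)
    if config.model_id == "xgboost":
        class_order = sorted(set(y_train))
        to_int = {c: i for i, c in enumerate(class_order)}
        estimator.fit(X_train, np.array([to_int[c] for c in y_train]))
        proba = estimator.predict_proba(X_test)
        model_classes = class_order
        predicted = np.array([class_order[i] for i in estimator.predict(X_test)])
    elif config.model_id == "svm":
        estimator.fit(X_train, y_train)
        margins = estimator.decision_function(X_test)
        if margins.ndim == 1:  # binary: single margin for classes_[1]
            margins = np.column_stack([-margins, margins])
        shifted = margins - margins.max(axis=1, keepdims=True)
        proba = np.exp(shifted)
        proba /= proba.sum(axis=1, keepdims=True)
        model_classes = list(estimator.classes_)
        predicted = estimator.predict(X_test)
    else:
        estimator.fit(X_train, y_train)
        proba = estimator.predict_proba(X_test)
        model_classes = list(estimator.classes_)
        predicted = estimator.predict(X_test)
    scores = np.zeros((len(X_test), len(classes)))
    for i, label in enumerate(model_classes):
        scores[:, classes.index(label)] = proba[:, i]
    return predicted, scores


def train_predict(
    train_records: Sequence[LabeledRecord],
    test_sequences: Sequence[RnaSequence],
    featurizer,
    model: ModelConfig,
    seed: int = 0,
    schema: Sequence[str] = DEFAULT_SCHEMA,
) -> tuple[list[str], np.ndarray]:
    """Fit on the training records and score the test sequences.

    Returns predicted labels and a row-stochastic score matrix with one
    column per schema class.
    """
    if not train_records:
        raise ValueError("empty training set")
    X_train, _ = encode_many([r.sequence for r in train_records], featurizer)
    X_test, _ = encode_many(list(test_sequences), featurizer)
    y_train = np.array([r.locality for r in train_records])
    predicted, scores = _fit_predict_arrays(
        model, X_train, y_train, X_test, seed, tuple(schema)
    )
    return list(predicted), scores


@dataclass
class CvResult:
    """Per-fold metric reports, their mean, and the seeded fold assignment."""

    fold_reports: list[MetricReport]
    mean_report: MetricReport
    fold_assignment: np.ndarray
    n_folds: int
    featurizer: object = None
    model: ModelConfig | None = None

    def summary(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "mean": self.mean_report.as_dict(),
            "folds": [r.as_dict() for r in self.fold_reports],
        }


def _mean_report(reports: Sequence[MetricReport]) -> MetricReport:
    aurocs = [r.auroc_macro for r in reports if r.auroc_macro is not None]
    per_class_keys = sorted({k for r in reports for k in r.auroc_per_class})
    per_class = {
        k: float(np.mean([r.auroc_per_class[k] for r in reports if k in r.auroc_per_class]))
        for k in per_class_keys
    }
    return MetricReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        specificity_macro=float(np.mean([r.specificity_macro for r in reports])),
        f1_macro=float(np.mean([r.f1_macro for r in reports])),
        mcc_macro=float(np.mean([r.mcc_macro for r in reports])),
        auroc_macro=float(np.mean(aurocs)) if aurocs else None,
        auroc_per_class=per_class,
        undefined_classes=tuple(
            sorted({c for r in reports for c in r.undefined_classes})
        ),
    )


def _as_records(dataset) -> list[LabeledRecord]:
    if isinstance(dataset, PreparedDataset):
        return list(dataset.records)
    return list(dataset)


def cross_validate(
    dataset,
    featurizer,
    model: ModelConfig,
    folds: int = 10,
    seed: int = 0,
    schema: Sequence[str] = DEFAULT_SCHEMA,
) -> CvResult:
    """Stratified seeded k-fold cross-validation of one featurizer/model pair.

    Records are sorted by id before fold assignment so that input order never
    changes the folds. If the smallest class has fewer members than ``folds``
    the fold count is downgraded (with a warning) to keep stratification
    feasible; a class with fewer than 2 members is an error.
    """
    records = sorted(_as_records(dataset), key=lambda r: r.sequence.id)
    labels = [r.locality for r in records]
    smallest = min(np.unique(labels, return_counts=True)[1])
    if smallest < 2:
        raise ValueError("every class needs at least 2 members for CV")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if smallest < folds:
        warnings.warn(
            f"smallest class has {smallest} members; downgrading {folds}-fold "
            f"CV to {smallest}-fold",
            stacklevel=2,
        )
        folds = int(smallest)
    X, _ = encode_many([r.sequence for r in records], featurizer)
    y = np.array(labels)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(records), dtype=np.int64)
    reports: list[MetricReport] = []
    classes = tuple(schema)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        assignment[test_idx] = fold
        predicted, scores = _fit_predict_arrays(
            model, X[train_idx], y[train_idx], X[test_idx], seed, classes
        )
        cm = confusion_matrix(list(y[test_idx]), list(predicted), classes)
        reports.append(metrics(cm, scores=scores, true_labels=list(y[test_idx])))
    return CvResult(
        fold_reports=reports,
        mean_report=_mean_report(reports),
        fold_assignment=assignment,
        n_folds=folds,
        featurizer=featurizer,
        model=model,
    )


# --- grid search ---------------------------------------------------------------

def _featurizer_label(featurizer) -> str:
    return featurizer.label()


def _validate_grid(featurizers, models) -> None:
    if not featurizers or not models:
        raise ValueError("grids must be non-empty")
    lo_k, hi_k = GRID_BOUNDS["k"]
    lo_g, hi_g = GRID_BOUNDS["gap"]

    def check_descriptor(config: DescriptorConfig) -> None:
        if config.k is not None and not lo_k <= config.k <= hi_k:
            raise ModelConfigError(
                f"{config.label()}: k outside grid bounds [{lo_k}, {hi_k}]"
            )
        if config.gap is not None and not lo_g <= config.gap <= hi_g:
            raise ModelConfigError(
                f"{config.label()}: gap outside grid bounds [{lo_g}, {hi_g}]"
            )

    for featurizer in featurizers:
        if isinstance(featurizer, DescriptorConfig):
            check_descriptor(featurizer)
        elif isinstance(featurizer, FusionSpec):
            for component in featurizer.components:
                check_descriptor(component)
        else:
            raise ModelConfigError(f"unsupported featurizer {featurizer!r}")
    lo_e, hi_e = GRID_BOUNDS["n_estimators"]
    lo_s, hi_s = GRID_BOUNDS["var_smoothing"]
    for model in models:
        hp = model.hp
        n_est = hp.get("n_estimators")
        if n_est is not None and not lo_e <= int(n_est) <= hi_e:
            raise ModelConfigError(
                f"{model.label()}: n_estimators outside [{lo_e}, {hi_e}]"
            )
        criterion = hp.get("criterion")
        if criterion is not None and criterion not in GRID_BOUNDS["criterion"]:
            raise ModelConfigError(f"{model.label()}: bad criterion {criterion!r}")
        kernel = hp.get("kernel")
        if kernel is not None and kernel not in GRID_BOUNDS["kernel"]:
            raise ModelConfigError(f"{model.label()}: bad kernel {kernel!r}")
        smoothing = hp.get("var_smoothing")
        if smoothing is not None and not lo_s <= float(smoothing) <= hi_s:
            raise ModelConfigError(
                f"{model.label()}: var_smoothing outside [{lo_s}, {hi_s}]"
            )


@dataclass
class GridSearchResult:
    best_featurizer: object
    best_model: ModelConfig
    best_result: CvResult
    leaderboard: list[tuple[object, ModelConfig, CvResult]]

    def summary(self) -> dict:
        return {
            "best": {
                "featurizer": _featurizer_label(self.best_featurizer),
                "model": self.best_model.label(),
                "mean": self.best_result.mean_report.as_dict(),
            },
            "leaderboard": [
                {
                    "featurizer": _featurizer_label(f),
                    "model": m.label(),
                    "mean_accuracy": r.mean_report.accuracy,
                    "mean_f1_macro": r.mean_report.f1_macro,
                }
                for f, m, r in self.leaderboard
            ],
        }


def grid_search(
    dataset,
    featurizer_grid: Sequence[object],
    model_grid: Sequence[ModelConfig],
    folds: int = 10,
    seed: int = 0,
    schema: Sequence[str] = DEFAULT_SCHEMA,
) -> GridSearchResult:
    """Exhaustive evaluation of every featurizer x model pair.

    Best = highest mean accuracy, ties broken by higher macro F1 then by
    lexicographic (featurizer, model) label; the full leaderboard is retained
    in that order.
    """
    _validate_grid(featurizer_grid, model_grid)
    entries: list[tuple[object, ModelConfig, CvResult]] = []
    for featurizer, model in itertools.product(featurizer_grid, model_grid):
        result = cross_validate(
            dataset, featurizer, model, folds=folds, seed=seed, schema=schema
        )
        entries.append((featurizer, model, result))
    entries.sort(
        key=lambda e: (
            -e[2].mean_report.accuracy,
            -e[2].mean_report.f1_macro,
            _featurizer_label(e[0]),
            e[1].label(),
        )
    )
    best_featurizer, best_model, best_result = entries[0]
    return GridSearchResult(
        best_featurizer=best_featurizer,
        best_model=best_model,
        best_result=best_result,
        leaderboard=entries,
    )
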
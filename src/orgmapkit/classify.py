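"""Compartment classification of profiles by support vector machines.

Marker proteins with established single-compartment localization train an
RBF-kernel SVM on their normalized abundance profiles (the replicate
profiles of one condition concatenated into one feature vector).  The C and
gamma hyperparameters are chosen by a grid search with fivefold
cross-validation; when several experiments are classified together, one
shared (C, gamma) maximizes the summed CV accuracy across experiments, so
performance stays comparable.  Raw SVM scores are converted into
probabilities by cross-validated Platt scaling, and each protein is assigned
to its best-fitting compartment with a confidence class derived from the
calibrated probability:

    >0.95 very high, >0.8 high, >0.65 medium, >0.4 low, otherwise best guess

(strict inequalities: a probability of exactly 0.95 is "high").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .errors import AnalysisError, ConfigurationError
from .io import MarkerAnnotation
from .preprocessing import MapCollection

CONFIDENCE_BINS = (
    (0.95, "very high"),
    (0.80, "high"),
    (0.65, "medium"),
    (0.40, "low"),
)

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-2, 11))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-9, 4))


def confidence_class(probability: float) -> str:
    for cut, label in CONFIDENCE_BINS:
        if probability > cut:
            return label
    return "best guess"


@dataclass
class MarkerSplit:
    """Stratified train/test partition of marker proteins."""

    train_ids: list[str]
    test_ids: list[str]
    labels: pd.Series  # full marker annotation restricted to profiled ids
    seed: int

    @property
    def train_labels(self) -> pd.Series:
        return self.labels.loc[self.train_ids]

    @property
    def test_labels(self) -> pd.Series:
        return self.labels.loc[self.test_ids]


def partition_markers(
    markers: MarkerAnnotation,
    profiled_ids,
    test_fraction: float = 0.30,
    seed: int = 0,
) -> MarkerSplit:
    """Hold out ``test_fraction`` of markers, stratified by compartment.

    Per-class test counts round toward the nominal fraction; classes with a
    single profiled marker go entirely to the training set with a warning.
    """
    labels = markers.restrict(profiled_ids).labels
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for compartment in sorted(labels.unique()):
        ids = sorted(labels.index[labels == compartment])
        if len(ids) < 2:
            warnings.warn(
                f"compartment {compartment!r} has {len(ids)} profiled marker(s); "
                "placed entirely in the training set",
                stacklevel=2,
            )
            train.extend(ids)
            continue
        rng.shuffle(ids)
        n_test = int(round(len(ids) * test_fraction))
        n_test = min(max(n_test, 1), len(ids) - 1)
        test.extend(ids[:n_test])
        train.extend(ids[n_test:])
    return MarkerSplit(
        train_ids=sorted(train), test_ids=sorted(test), labels=labels, seed=seed
    )


@dataclass
class ClassifierState:
    """A fitted per-experiment SVM with its shared hyperparameters."""

    C: float
    gamma: float
    estimator: CalibratedClassifierCV
    classes: list[str]
    condition: str
    feature_columns: pd.MultiIndex

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ConfigurationError("C and gamma must be positive")


def _features(
    collection: MapCollection, condition: str, ids
) -> pd.DataFrame:
    return collection.stacked(condition, ids=ids)


def _cv_accuracy(X, y, C, gamma, cv, seed) -> float:
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    return float(cross_val_score(svc, X, y, cv=folds).mean())


def tune_and_train(
    collections: list[MapCollection],
    split: MarkerSplit,
    conditions: list[str] | None = None,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    cv: int = 5,
    refine: bool = True,
    seed: int = 0,
) -> list[ClassifierState]:
    """Grid-search shared (C, gamma) and fit one SVM per experiment.

    At each grid point SVMs are cross-validated on each experiment's train
    markers and the optimum of the summed accuracy is taken; one refinement
    pass at half-step spacing around that optimum follows.  Final machines
    are fitted on the full train set with cross-validated probability
    calibration.
    """
    if len(c_grid) == 0 or len(gamma_grid) == 0:
        raise ConfigurationError("hyperparameter grid is empty")
    if conditions is None:
        conditions = [c.conditions[0] for c in collections]

    y = split.train_labels
    Xs = []
    for coll, cond in zip(collections, conditions):
        X = _features(coll, cond, split.train_ids)
        if X.isna().to_numpy().any():
            raise AnalysisError("train markers must be complete in all experiments")
        Xs.append(X.to_numpy())
    y_arr = y.loc[split.train_ids].to_numpy()

    def summed_accuracy(C, gamma) -> float:
        return sum(_cv_accuracy(X, y_arr, C, gamma, cv, seed) for X in Xs)

    scores = {
        (C, g): summed_accuracy(C, g) for C in c_grid for g in gamma_grid
    }
    (best_c, best_gamma) = max(scores, key=lambda k: (scores[k], -k[0], -k[1]))

    if refine:
        steps = (2.0 ** -0.5, 1.0, 2.0 ** 0.5)
        for C in (best_c * s for s in steps):
            for g in (best_gamma * s for s in steps):
                if (C, g) not in scores:
                    scores[(C, g)] = summed_accuracy(C, g)
        (best_c, best_gamma) = max(
            scores, key=lambda k: (scores[k], -k[0], -k[1])
        )

    states = []
    for coll, cond in zip(collections, conditions):
        X = _features(coll, cond, split.train_ids)
        # fivefold cross-validated Platt scaling of the raw SVM scores
        svc = CalibratedClassifierCV(
            SVC(kernel="rbf", C=best_c, gamma=best_gamma),
            method="sigmoid",
            cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
            ensemble=False,
        )
        svc.fit(X.to_numpy(), y_arr)
        states.append(
            ClassifierState(
                C=best_c,
                gamma=best_gamma,
                estimator=svc,
                classes=list(svc.classes_),
                condition=cond,
                feature_columns=X.columns,
            )
        )
    return states


@dataclass
class ClassificationResult:
    """Predicted compartments with calibrated probabilities."""

    table: pd.DataFrame  # columns: compartment, probability, confidence_class
    probabilities: pd.DataFrame  # per-class calibrated probabilities

    def confidence_counts(self) -> pd.Series:
        order = ["very high", "high", "medium", "low", "best guess"]
        return self.table["confidence_class"].value_counts().reindex(order, fill_value=0)


def predict_with_confidence(
    state: ClassifierState,
    features: pd.DataFrame | MapCollection,
) -> ClassificationResult:
    """Assign every profiled protein to its best-fitting compartment.

    The winning class is the argmax of the calibrated probabilities, so the
    reported probability always belongs to the predicted class.
    """
    if isinstance(features, MapCollection):
        features = features.stacked(state.condition)
    if features.shape[1] != len(state.feature_columns):
        raise AnalysisError(
            f"expected {len(state.feature_columns)} features, "
            f"got {features.shape[1]}"
        )
    proba = state.estimator.predict_proba(features.to_numpy())
    winners = np.argmax(proba, axis=1)
    p_win = proba[np.arange(len(proba)), winners]
    table = pd.DataFrame(
        {
            "compartment": np.asarray(state.classes)[winners],
            "probability": p_win,
            "confidence_class": [confidence_class(p) for p in p_win],
        },
        index=features.index,
    )
    return ClassificationResult(
        table=table,
        probabilities=pd.DataFrame(
            proba, index=features.index, columns=state.classes
        ),
    )


@dataclass
class PerformanceReport:
    """Held-out marker evaluation of one fitted classifier."""

    confusion: pd.DataFrame  # true class x predicted class, counts
    per_class: pd.DataFrame  # recall, precision, f1, support
    overall_f1: float  # micro-averaged == proportion correctly predicted
    macro_f1: float
    subsample_mean: pd.Series
    subsample_sd: pd.Series


def _scores_from_confusion(confusion: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    tp = pd.Series(np.diag(confusion.to_numpy()), index=confusion.index, dtype=float)
    support = confusion.sum(axis=1).astype(float)
    predicted = confusion.sum(axis=0).astype(float).reindex(confusion.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = tp / support
        precision = tp / predicted
        f1 = 2 * recall * precision / (recall + precision)
    f1 = f1.where((recall + precision) > 0, 0.0)
    per_class = pd.DataFrame(
        {
            "recall": recall,
            "precision": precision,
            "f1": f1,
            "support": support.astype(int),
        }
    )
    total = float(support.sum())
    overall = float(tp.sum() / total) if total else np.nan
    macro = float(f1.loc[support > 0].mean()) if total else np.nan
    return per_class, overall, macro


def evaluate_markers(
    state: ClassifierState,
    split: MarkerSplit,
    features: pd.DataFrame | MapCollection,
    n_subsamples: int = 20,
    subsample_fraction: float = 0.75,
    seed: int = 0,
) -> PerformanceReport:
    """Misclassification matrix and F1 scores on the held-out markers.

    Score variability is assessed by sub-sampling the test set
    ``n_subsamples`` times (class-stratified ``subsample_fraction``) and
    reporting mean +- standard deviation.
    """
    if not split.test_ids:
        raise AnalysisError("the hold-out test set is empty")
    if isinstance(features, MapCollection):
        features = features.stacked(state.condition)
    X = features.loc[split.test_ids]
    y_true = split.test_labels
    result = predict_with_confidence(state, X)
    y_pred = result.table["compartment"]

    classes = sorted(set(state.classes) | set(y_true.unique()))
    confusion = pd.crosstab(y_true, y_pred).reindex(
        index=classes, columns=classes, fill_value=0
    )
    confusion.index.name = "true"
    confusion.columns.name = "predicted"
    per_class, overall, macro = _scores_from_confusion(confusion)

    rng = np.random.default_rng(seed)
    sub_scores = {"overall_f1": [], "macro_f1": []}
    for _ in range(n_subsamples):
        chosen: list[str] = []
        for compartment in sorted(y_true.unique()):
            ids = sorted(y_true.index[y_true == compartment])
            n = max(1, int(round(len(ids) * subsample_fraction)))
            chosen.extend(rng.choice(ids, size=n, replace=False))
        sub_conf = pd.crosstab(
            y_true.loc[chosen], y_pred.loc[chosen]
        ).reindex(index=classes, columns=classes, fill_value=0)
        _, sub_overall, sub_macro = _scores_from_confusion(sub_conf)
        sub_scores["overall_f1"].append(sub_overall)
        sub_scores["macro_f1"].append(sub_macro)

    mean = pd.Series({k: float(np.mean(v)) for k, v in sub_scores.items()})
    sd = pd.Series({k: float(np.std(v, ddof=1)) for k, v in sub_scores.items()})
    return PerformanceReport(
        confusion=confusion,
        per_class=per_class,
        overall_f1=overall,
        macro_f1=macro,
        subsample_mean=mean,
        subsample_sd=sd,
    )


def read_misclassification_matrix(path) -> pd.DataFrame:
    """Import a class-labeled misclassification matrix from an external tool."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "true"
    matrix.columns.name = "predicted"
    return matrix


def write_misclassification_matrix(confusion: pd.DataFrame, path) -> None:
    confusion.to_csv(path, sep="\t")
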
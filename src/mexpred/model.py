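"""Classification layer: SVM on transfer components, KNN fallback.

The margin classifier is trained on the transferred source (microindel)
components and evaluated by stratified 10-fold cross-validation; the
fitted model then assigns each target microexon a functional probability
which is thresholded (default 0.5) into a binary call. Because the TCA
embedding is defined only for the cohorts it was fitted on, a single
novel microexon is handled by a k-nearest-neighbor fallback in the
original standardized 25-feature space: its probability is the mean of
the probabilities already assigned to its k=5 nearest cataloged
microexons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .tca import median_heuristic_gamma

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5
DEFAULT_K = 5
DEFAULT_N_FOLDS = 10
#: Default seed for fold assignment and Platt calibration.
DEFAULT_SEED = 20211126


@dataclass(frozen=True)
class SVMConfig:
    """Support-vector classifier settings.

    ``gamma=None`` means the median pairwise-distance heuristic on the
    training matrix (RBF only); probabilities come from Platt scaling
    inside the SVM fit.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None

    def resolve_gamma(self, X: np.ndarray) -> float | str:
        if self.kernel != "rbf":
            return "scale"
        return median_heuristic_gamma(X) if self.gamma is None else self.gamma


@dataclass
class EvaluationReport:
    """Pooled cross-validation metrics for a binary classifier."""

    precision: float
    accuracy: float
    mcc: float
    recall: float
    auc: float
    n_folds: int
    fold_assignments: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "recall": self.recall,
            "auc": self.auc,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PredictionRecord:
    """One record's functional probability and thresholded call.

    ``route`` records whether the probability came from the TCA+SVM
    pipeline or the KNN fallback. A probability exactly at the threshold
    is called functional.
    """

    record_id: str
    probability: float
    threshold: float
    route: str

    @property
    def label(self) -> str:
        return "functional" if self.probability >= self.threshold else "neutral"


@dataclass
class ReferenceCatalog:
    """Already-scored microexons backing the KNN fallback.

    ``features`` live in the original standardized 25-feature space;
    ``probabilities`` are the TCA+SVM scores assigned when the catalog
    was built.
    """

    features: np.ndarray
    probabilities: np.ndarray
    record_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("catalog features must be a matrix")
        if len(self.probabilities) != len(self.features):
            raise ValueError("one probability per catalog row required")
        if not self.record_ids:
            self.record_ids = [f"catalog{i}" for i in range(len(self.features))]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceCatalog":
        catalog = joblib.load(Path(path))
        if not isinstance(catalog, cls):
            raise TypeError(f"{path} does not contain a ReferenceCatalog")
        return catalog


# ---------------------------------------------------------------------------
# metrics


def binary_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, probabilities: np.ndarray
) -> dict[str, float]:
    """Precision, accuracy, MCC, recall from the 2x2 confusion counts and
    AUC as the rank statistic over probabilities."""
    return {
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "auc": float(roc_auc_score(y_true, probabilities)),
    }


# ---------------------------------------------------------------------------
# training & cross-validation


def train_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    config: SVMConfig = SVMConfig(),
    seed: int = DEFAULT_SEED,
) -> SVC:
    """Fit a probability-calibrated SVM; deterministic for a given seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels must contain both classes")
    model = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.resolve_gamma(X),
        probability=True,  # Platt scaling inside the fit
        random_state=seed,
    )
    with warnings.catch_warnings():
        # scikit-learn >= 1.9 deprecates probability=True in favor of an
        # external calibration wrapper; the in-fit Platt scaling is the
        # behavior this model specifies, so keep it while it exists.
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X, y)
    return model


def cross_validate(
    features: np.ndarray,
    labels: Sequence[int],
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = DEFAULT_SEED,
    config: SVMConfig = SVMConfig(),
) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled test predictions.

    Each record is scored exactly once, by the model trained on the
    other folds; metrics are computed over the pooled predictions. If a
    training split ever ends up single-class the folds are re-drawn with
    a shifted seed (a handful of attempts, then fatal).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("cross-validation requires both classes")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    last_error: Exception | None = None
    for attempt in range(3):
        fold_seed = seed + attempt
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        probabilities = np.full(len(y), np.nan)
        assignments = np.full(len(y), -1, dtype=int)
        try:
            for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
                if np.unique(y[train_idx]).size < 2:
                    raise ValueError(f"fold {fold} training split is single-class")
                model = train_classifier(X[train_idx], y[train_idx], config, fold_seed)
                probabilities[test_idx] = model.predict_proba(X[test_idx])[:, 1]
                assignments[test_idx] = fold
        except ValueError as exc:
            last_error = exc
            logger.warning("re-stratifying folds (attempt %d): %s", attempt + 1, exc)
            continue
        predictions = (probabilities >= DEFAULT_THRESHOLD).astype(int)
        metrics = binary_metrics(y, predictions, probabilities)
        return EvaluationReport(
            precision=metrics["precision"],
            accuracy=metrics["accuracy"],
            mcc=metrics["mcc"],
            recall=metrics["recall"],
            auc=metrics["auc"],
            n_folds=n_folds,
            fold_assignments=assignments,
            seed=fold_seed,
        )
    raise ValueError(f"could not stratify {n_folds} folds: {last_error}")


# ---------------------------------------------------------------------------
# prediction


def predict_target(
    model: SVC,
    components: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    record_ids: Sequence[str] | None = None,
) -> list[PredictionRecord]:
    """Score target-domain embeddings with the trained SVM."""
    X = np.atleast_2d(np.asarray(components, dtype=float))
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"component dimension {X.shape[1]} does not match model "
            f"dimension {model.n_features_in_}"
        )
    if record_ids is None:
        record_ids = [f"target{i}" for i in range(len(X))]
    if len(record_ids) != len(X):
        raise ValueError("record_ids length must match components")
    probabilities = model.predict_proba(X)[:, 1]
    return [
        PredictionRecord(str(rid), float(p), threshold, "tca_svm")
        for rid, p in zip(record_ids, probabilities)
    ]


def knn_predict(
    catalog: ReferenceCatalog,
    query: np.ndarray,
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
    record_ids: Sequence[str] | None = None,
) -> list[PredictionRecord]:
    """Score novel records as the mean probability of their k nearest
    cataloged microexons (Euclidean distance, standardized features)."""
    if len(catalog.features) < k:
        raise ValueError(
            f"catalog has {len(catalog.features)} rows; k={k} requires at least k"
        )
    Q = np.atleast_2d(np.asarray(query, dtype=float))
    if Q.shape[1] != catalog.features.shape[1]:
        raise ValueError("query dimension does not match catalog")
    if record_ids is None:
        record_ids = [f"query{i}" for i in range(len(Q))]
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(catalog.features)
    _, indices = nn.kneighbors(Q)
    probabilities = catalog.probabilities[indices].mean(axis=1)
    return [
        PredictionRecord(str(rid), float(p), threshold, "knn")
        for rid, p in zip(record_ids, probabilities)
    ]


def count_at_threshold(
    predictions: Iterable[PredictionRecord] | Sequence[float] | np.ndarray,
    threshold: float,
) -> int:
    """Number of predictions with probability at or above the threshold.

    Accepts prediction records or bare probabilities.
    """
    probabilities = [
        p.probability if isinstance(p, PredictionRecord) else float(p)
        for p in predictions
    ]
    return int(sum(p >= threshold for p in probabilities))


def predictions_to_frame(predictions: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Tabular view of predictions (TSV-friendly)."""
    return pd.DataFrame(
        {
            "record_id": [p.record_id for p in predictions],
            "probability": [p.probability for p in predictions],
            "label": [p.label for p in predictions],
            "threshold": [p.threshold for p in predictions],
            "route": [p.route for p in predictions],
        }
    )
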
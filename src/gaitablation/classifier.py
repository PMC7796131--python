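"""Leave-one-trial-out Gaussian-SVM classification on PC scores.

Each fold reserves one whole trial for testing; z-scoring and PCA are
fit on the training trials only and the held-out trial is projected
with the training loadings (no separate PCA on test data).  A Gaussian
(RBF) kernel SVM with one-vs-one multiclass decomposition separates
stand/walk/run/sprint in the space of the first three principal
components.  Accuracy is also scored with run and sprint merged into a
single class, since their difference is speed rather than biomechanics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import pairwise_distances
from sklearn.svm import SVC

from .features import FeatureMatrix, apply_normalizer, concat_feature_matrices, fit_normalizer
from .pca_similarity import fit_pca, transform
from .synthetic_data import ACTIVITIES

__all__ = [
    "SVMConfig",
    "CVResult",
    "MERGED_CLASSES",
    "cross_validate",
    "merge_run_sprint",
    "confusion_matrix",
    "sensitivity_specificity",
    "median_mad",
]

MERGED_CLASSES: tuple[str, ...] = ("stand", "walk", "run_sprint")
_MERGE = {"stand": "stand", "walk": "walk", "run": "run_sprint", "sprint": "run_sprint"}


@dataclass
class SVMConfig:
    """Gaussian-kernel SVM hyperparameters.

    ``gamma=None`` selects the median-pairwise-distance heuristic on
    the training scores: gamma = 1 / (2 s^2) with s the median
    Euclidean distance over a seeded subsample of training rows.
    """

    C: float = 1.0
    gamma: float | None = None
    heuristic_subsample: int = 512


@dataclass
class CVResult:
    """Fold-wise and pooled outcomes of a leave-one-trial-out CV."""

    fold_trials: list[str]
    fold_accuracy: np.ndarray
    fold_accuracy_merged: np.ndarray
    confusion: np.ndarray  # 4x4, rows = true class in ACTIVITIES order
    confusion_merged: np.ndarray  # 3x3 in MERGED_CLASSES order
    sensitivity: dict[str, float] = field(default_factory=dict)
    specificity: dict[str, float] = field(default_factory=dict)
    skipped_folds: list[str] = field(default_factory=list)
    fold_predictions: list[np.ndarray] = field(default_factory=list)

    @property
    def accuracy_median(self) -> float:
        return median_mad(self.fold_accuracy)[0]

    @property
    def accuracy_mad(self) -> float:
        return median_mad(self.fold_accuracy)[1]

    @property
    def merged_median(self) -> float:
        return median_mad(self.fold_accuracy_merged)[0]

    @property
    def merged_mad(self) -> float:
        return median_mad(self.fold_accuracy_merged)[1]


def merge_run_sprint(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    """Map run and sprint to a single run_sprint class."""
    labels = np.asarray(labels, dtype=object)
    unknown = set(labels.tolist()) - set(ACTIVITIES)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    return np.array([_MERGE[l] for l in labels.tolist()], dtype=object)


def confusion_matrix(true: np.ndarray, pred: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        out[index[t], index[p]] += 1
    return out


def sensitivity_specificity(conf: np.ndarray, class_index: int) -> tuple[float, float]:
    """One-vs-rest sensitivity and specificity for one class.

    An empty denominator (no true members, or no true negatives)
    yields NaN rather than 0, flagging the value as undefined.
    """
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1] or np.any(conf < 0):
        raise ValueError("confusion matrix must be square and non-negative")
    tp = conf[class_index, class_index]
    fn = conf[class_index].sum() - tp
    fp = conf[:, class_index].sum() - tp
    tn = conf.sum() - tp - fn - fp
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return float(sens), float(spec)


def median_mad(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Median and unscaled median absolute deviation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median_mad of an empty sequence")
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


def _select_gamma(scores: np.ndarray, config: SVMConfig, rng: np.random.Generator) -> float:
    if config.gamma is not None:
        return config.gamma
    n = scores.shape[0]
    take = min(config.heuristic_subsample, n)
    idx = rng.choice(n, size=take, replace=False)
    d = pairwise_distances(scores[idx])
    med = float(np.median(d[np.triu_indices(take, k=1)]))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


def cross_validate(
    trial_matrices: Sequence[FeatureMatrix],
    k_components: int = 3,
    svm: SVMConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Leave-one-trial-out CV over one subject's trials.

    Per fold: fit the z-score normalizer and PCA on the training
    trials, keep the first min(k, n_features) scores, train the SVM,
    then normalise and project the held-out trial with the training
    statistics and score it.  Folds whose training data lack one of
    the four classes are skipped with a warning.
    """
    if len(trial_matrices) < 2:
        raise ValueError("need at least two trials for leave-one-trial-out CV")
    svm = svm or SVMConfig()
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(len(trial_matrices))

    fold_trials: list[str] = []
    acc_raw: list[float] = []
    acc_merged: list[float] = []
    skipped: list[str] = []
    predictions: list[np.ndarray] = []
    conf = np.zeros((4, 4), dtype=int)
    conf_merged = np.zeros((3, 3), dtype=int)

    for i, test_fm in enumerate(trial_matrices):
        train = concat_feature_matrices([m for j, m in enumerate(trial_matrices) if j != i])
        if set(ACTIVITIES) - set(train.labels.tolist()):
            warnings.warn(
                f"fold {test_fm.trial_id}: training data lack a class; fold skipped",
                stacklevel=2,
            )
            skipped.append(test_fm.trial_id)
            continue
        rng = np.random.default_rng(fold_seeds[i])
        norm = fit_normalizer(train)
        train_z = apply_normalizer(norm, train)
        test_z = apply_normalizer(norm, test_fm)
        k = min(k_components, train_z.values.shape[1])
        model = fit_pca(train_z, n_components=k)
        train_scores = model.scores[:, :k]
        test_scores = transform(model, test_z)[:, :k]

        gamma = _select_gamma(train_scores, svm, rng)
        clf = SVC(C=svm.C, kernel="rbf", gamma=gamma, cache_size=500)
        clf.fit(train_scores, train.labels.astype(str))
        pred = clf.predict(test_scores).astype(object)

        true = test_fm.labels
        acc_raw.append(float(np.mean(pred == true)))
        true_m = merge_run_sprint(true)
        pred_m = merge_run_sprint(pred)
        acc_merged.append(float(np.mean(pred_m == true_m)))
        conf += confusion_matrix(true, pred, ACTIVITIES)
        conf_merged += confusion_matrix(true_m, pred_m, MERGED_CLASSES)
        fold_trials.append(test_fm.trial_id)
        predictions.append(pred)

    sens = {}
    spec = {}
    for idx, cls in enumerate(ACTIVITIES):
        sens[cls], spec[cls] = sensitivity_specificity(conf, idx)
    return CVResult(
        fold_trials=fold_trials,
        fold_accuracy=np.array(acc_raw),
        fold_accuracy_merged=np.array(acc_merged),
        confusion=conf,
        confusion_merged=conf_merged,
        sensitivity=sens,
        specificity=spec,
        skipped_folds=skipped,
        fold_predictions=predictions,
    )
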
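"""PCA fitting, cross-trial component-angle similarity and diagnostics.

Each trial's normalized feature matrix is decomposed into orthonormal
principal axes.  Similarity between trials (and subjects) is measured
by the angle between loading vectors: for every unordered pair of
fitted models and every pair of component indices (i, j) the angle is
arccos of the loading dot product; angles between like-components
(i == j) are folded into [0, 90] degrees by taking the supplementary
angle, since a principal axis is direction-ambiguous.  The reported
matrix holds the median angle per (i, j) across all pairs.

Diagnostics correlate a component's scores with a per-window reference
series (windowed treadmill speed for PC1, windowed left-minus-right
plate force for PC2), taking |rho| per trial because component signs
are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .features import FeatureMatrix

__all__ = [
    "PCAModel",
    "AngleMatrix",
    "CorrelationResult",
    "fit_pca",
    "transform",
    "component_angle",
    "fold_angle",
    "pairwise_component_angles",
    "angle_matrix",
    "pc_correlation",
]


@dataclass
class PCAModel:
    """Orthonormal loadings, training scores and variance fractions."""

    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_windows, n_components) of the training data
    feature_ids: list[str]
    subject_id: str = ""
    trial_id: str = ""

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def loadings_frame(self):
        """Loadings as a features x components table for export."""
        import pandas as pd

        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.loadings, index=self.feature_ids, columns=cols)

    def scores_frame(self):
        """Training scores as a windows x components table for export."""
        import pandas as pd

        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, columns=cols)


@dataclass
class AngleMatrix:
    """k x k median folded angles (degrees) across model pairs."""

    values: np.ndarray
    n_pairs: int


@dataclass
class CorrelationResult:
    """Per-trial |rho| between component scores and a reference series."""

    per_trial: np.ndarray
    median: float
    iqr: float


def fit_pca(fm: FeatureMatrix, n_components: int | None = None) -> PCAModel:
    """Full PCA of a normalized feature matrix.

    Components are ordered by decreasing explained variance with a
    deterministic sign convention: the largest-magnitude entry of each
    loading column is positive.
    """
    if fm.n_windows < 2:
        raise ValueError("PCA needs at least 2 rows")
    k = n_components or min(fm.values.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(fm.values)
    loadings = pca.components_.T.copy()  # (features, components)
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores = scores * flip
    return PCAModel(
        loadings=loadings,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        feature_ids=list(fm.feature_ids),
        subject_id=fm.subject_id,
        trial_id=fm.trial_id,
    )


def transform(model: PCAModel, fm: FeatureMatrix) -> np.ndarray:
    """Project held-out data with the training model's mean and loadings."""
    if model.feature_ids != fm.feature_ids:
        raise ValueError("feature ids do not match the fitted model")
    return (fm.values - model.mean) @ model.loadings


def component_angle(w_a: np.ndarray, w_b: np.ndarray) -> float:
    """Angle in degrees between two loading vectors, in [0, 180]."""
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if w_a.shape != w_b.shape:
        raise ValueError("loading vectors have different dimensions")
    denom = np.linalg.norm(w_a) * np.linalg.norm(w_b)
    if denom == 0:
        raise ValueError("zero-norm loading vector")
    return float(np.degrees(np.arccos(np.clip(np.dot(w_a, w_b) / denom, -1.0, 1.0))))


def fold_angle(theta: float, like_components: bool) -> float:
    """Supplementary-angle folding for like-components only.

    A principal axis is equivalent to its negation, so like-component
    angles above 90 degrees are reported as 180 - theta; non-like
    angles are left unchanged.
    """
    if not 0.0 <= theta <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    if like_components and theta > 90.0:
        return 180.0 - theta
    return theta


def pairwise_component_angles(models: Sequence[PCAModel], k: int = 3) -> np.ndarray:
    """(n_pairs, k, k) folded angles for every unordered model pair.

    Entry (p, i, j) is the angle between component i of the pair's
    first model and component j of its second; folding applies only on
    the diagonal (i == j).
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    ids = models[0].feature_ids
    for m in models[1:]:
        if m.feature_ids != ids:
            raise ValueError("models do not share a feature space")
        if m.n_components < k:
            raise ValueError("model has fewer components than requested")
    out = []
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            wa, wb = models[a].loadings, models[b].loadings
            block = np.empty((k, k))
            for i in range(k):
                for j in range(k):
                    block[i, j] = fold_angle(
                        component_angle(wa[:, i], wb[:, j]), like_components=(i == j)
                    )
            out.append(block)
    return np.array(out)


def angle_matrix(models: Sequence[PCAModel], k: int = 3) -> AngleMatrix:
    """Median folded angle per component pair across all model pairs."""
    blocks = pairwise_component_angles(models, k)
    return AngleMatrix(values=np.median(blocks, axis=0), n_pairs=blocks.shape[0])


def pc_correlation(
    scores_by_trial: Sequence[np.ndarray],
    reference_by_trial: Sequence[np.ndarray],
    method: str = "pearson",
) -> CorrelationResult:
    """|correlation| of one component's scores against a reference.

    Component direction is arbitrary, so the absolute value of each
    trial's correlation is taken before computing the median and IQR
    across trials.
    """
    if len(scores_by_trial) != len(reference_by_trial):
        raise ValueError("need one reference series per trial")
    rhos = []
    for s, r in zip(scores_by_trial, reference_by_trial):
        s = np.asarray(s, dtype=float)
        r = np.asarray(r, dtype=float)
        if s.shape != r.shape:
            raise ValueError("scores and reference have different lengths")
        if np.std(s) == 0 or np.std(r) == 0:
            raise ValueError("correlation undefined for a constant series")
        if method == "pearson":
            rho = np.corrcoef(s, r)[0, 1]
        elif method == "spearman":
            from scipy import stats

            rho = stats.spearmanr(s, r).statistic
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rhos.append(abs(float(rho)))
    rhos = np.array(rhos)
    q1, q3 = np.percentile(rhos, [25, 75])
    return CorrelationResult(per_trial=rhos, median=float(np.median(rhos)), iqr=float(q3 - q1))
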
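"""Shared fixtures: the default synthetic study and reusable helpers.

The heavy session-scoped fixtures are computed once and shared between
the module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gaitablation import (
    ACTIVITIES,
    FeatureMatrix,
    SubjectProfile,  # noqa: F401 - re-used by test modules
    default_profiles,
    extract_study_features,
    simulate_study,
)
from gaitablation.ablation import CANONICAL_CASES, run_ablation
from gaitablation.classifier import cross_validate
from gaitablation.features import apply_normalizer, fit_normalizer
from gaitablation.pca_similarity import fit_pca
from gaitablation.study import trial_references

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

#: Seed of the shared default study; replicate studies use seeds 0-9.
STUDY_SEED = 1234
N_REPLICATES = 10


@pytest.fixture(scope="session")
def subject2() -> SubjectProfile:
    return default_profiles()[1]


@pytest.fixture(scope="session")
def default_study():
    """Default study: 5 subjects x 6 trials of 150 s, plus features."""
    sessions = simulate_study(5, 6, seed=STUDY_SEED)
    feats = extract_study_features(sessions)
    return sessions, feats


@pytest.fixture(scope="session")
def trial_models(default_study):
    """Per-trial PCA models (self-normalized) with diagnostic references."""
    sessions, feats = default_study
    models, refs = [], []
    for sid, mats in feats.items():
        for sess, fm in zip(sessions[sid], mats):
            z = apply_normalizer(fit_normalizer(fm), fm)
            models.append(fit_pca(z))
            refs.append(trial_references(sess, fm.window_starts))
    return models, refs


@pytest.fixture(scope="session")
def case1_cv(default_study):
    """Full-sensor leave-one-trial-out CV for every subject."""
    _, feats = default_study
    return {
        sid: cross_validate(mats, seed=STUDY_SEED + i)
        for i, (sid, mats) in enumerate(feats.items())
    }


@pytest.fixture(scope="session")
def replicate_case_medians():
    """Per-replicate median merged accuracies of Cases 2, 3 and 5.

    Ten replicate default studies (seeds 0-9); each runs the full
    ablation pipeline for the upper-leg, lower-leg and lower-leg+plates
    cases.
    """
    cases = [CANONICAL_CASES[i] for i in (2, 3, 5)]
    rows = []
    for seed in range(N_REPLICATES):
        sessions = simulate_study(5, 6, seed=seed)
        feats = extract_study_features(sessions)
        result = run_ablation(feats, cases=cases, seed=seed)
        for cid in (2, 3, 5):
            rows.append(
                {"seed": seed, "case": cid, "median_merged": result.case_median(cid)}
            )
    return pd.DataFrame(rows)


_CENTERS = {
    "stand": np.array([0.0, 0.0, 0.0]),
    "walk": np.array([1.0, 0.0, 0.0]),
    "run": np.array([0.0, 1.0, 0.0]),
    "sprint": np.array([0.0, 0.0, 1.0]),
}


def make_blob_trials(
    n_trials: int = 2,
    n_per_class: int | dict[str, int] = 100,
    separation: float = 8.0,
    noise: float = 0.5,
    seed: int = 0,
    shuffle_labels: bool = False,
) -> list[FeatureMatrix]:
    """Gaussian class blobs packaged as per-trial feature matrices."""
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(n_trials):
        xs, ys = [], []
        for cls in ACTIVITIES:
            n = n_per_class[cls] if isinstance(n_per_class, dict) else n_per_class
            xs.append(separation * _CENTERS[cls] + rng.normal(0, noise, (n, 3)))
            ys += [cls] * n
        values = np.vstack(xs)
        labels = np.array(ys, dtype=object)
        if shuffle_labels:
            labels = rng.permutation(labels)
        trials.append(
            FeatureMatrix(
                values=values,
                feature_ids=["f1", "f2", "f3"],
                window_starts=np.arange(len(labels)) * 0.2,
                labels=labels,
                subject_id="blob",
                trial_id=f"blob_t{t + 1}",
            )
        )
    return trials
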
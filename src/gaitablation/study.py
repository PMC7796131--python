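"""Study-level glue: simulate all subjects, label, extract, reference.

A "study" is the default protocol: five subjects (the five built-in
threshold profiles), six 150 s trials each, with per-subject trial
schedules that jointly cover every ordered activity-pair transition.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import labelling
from .features import FeatureMatrix, extract_features, full_feature_specs
from .synthetic_data import (
    SessionRecording,
    SimulationConfig,
    SubjectProfile,
    default_profiles,
    full_channel_specs,
    generate_session,
    generate_study_schedules,
)

__all__ = [
    "simulate_study",
    "session_labels",
    "session_features",
    "extract_study_features",
    "windowed_reference",
    "trial_references",
]


def simulate_study(
    n_subjects: int = 5,
    n_trials: int = 6,
    seed: int = 0,
    config: SimulationConfig | None = None,
    profiles: Sequence[SubjectProfile] | None = None,
) -> dict[str, list[SessionRecording]]:
    """Simulate ``n_subjects`` x ``n_trials`` sessions, deterministically.

    Profiles default to the five built-in threshold sets (cycled with a
    numeric suffix if more subjects are requested).
    """
    config = config or SimulationConfig()
    base = list(profiles) if profiles is not None else default_profiles()
    chosen: list[SubjectProfile] = []
    for i in range(n_subjects):
        p = base[i % len(base)]
        if i >= len(base):
            from dataclasses import replace

            p = replace(p, subject_id=f"{p.subject_id}r{i // len(base)}")
        chosen.append(p)

    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(2 * n_subjects)
    study: dict[str, list[SessionRecording]] = {}
    for i, profile in enumerate(chosen):
        schedules = generate_study_schedules(
            int(subject_seeds[2 * i]), n_trials, config.n_commands, config.command_duration
        )
        trial_ss = np.random.SeedSequence(int(subject_seeds[2 * i + 1]))
        trial_seeds = trial_ss.generate_state(n_trials)
        sessions = [
            generate_session(
                profile,
                trial_id=f"{profile.subject_id}_t{j + 1}",
                config=config,
                seed=int(trial_seeds[j]),
                schedule=schedules[j],
            )
            for j in range(n_trials)
        ]
        study[profile.subject_id] = sessions
    return study


def session_labels(
    session: SessionRecording,
    profile: SubjectProfile,
    config: SimulationConfig | None = None,
    smooth: bool = True,
) -> labelling.LabelSeries:
    """Truth labels from the recorded treadmill speed channel."""
    config = config or SimulationConfig()
    _, times, speeds = session.channel("speed")
    if smooth:
        speeds = np.clip(labelling.smooth_speed(times, speeds), 0.0, None)
    return labelling.label_by_speed(times, speeds, profile, stand_eps=config.stand_eps)


def session_features(
    session: SessionRecording,
    profile: SubjectProfile,
    config: SimulationConfig | None = None,
) -> FeatureMatrix:
    """Full 44-feature matrix of one session, labelled from speed."""
    config = config or SimulationConfig()
    specs = full_feature_specs(full_channel_specs(config))
    labels = session_labels(session, profile, config)
    return extract_features(session, specs, labels)


def extract_study_features(
    study: Mapping[str, Sequence[SessionRecording]],
    config: SimulationConfig | None = None,
    profiles: Sequence[SubjectProfile] | None = None,
) -> dict[str, list[FeatureMatrix]]:
    """Full-sensor feature matrices for every session in a study."""
    config = config or SimulationConfig()
    by_id = {p.subject_id: p for p in (profiles or default_profiles())}
    out: dict[str, list[FeatureMatrix]] = {}
    for subject_id, sessions in study.items():
        profile = by_id.get(subject_id)
        if profile is None:  # replicated subjects reuse their base profile
            base_id = subject_id.split("r")[0]
            profile = by_id[base_id]
        out[subject_id] = [session_features(s, profile, config) for s in sessions]
    return out


def windowed_reference(
    times: np.ndarray, values: np.ndarray, starts: np.ndarray, window: float = 0.5
) -> np.ndarray:
    """Per-window mean of a scalar stream on the feature window grid."""
    fs = 1.0 / float(np.median(np.diff(times)))
    n_per = int(round(window * fs))
    idx0 = np.round(np.asarray(starts) * fs).astype(int)
    return values[idx0[:, None] + np.arange(n_per)[None, :]].mean(axis=-1)


def trial_references(session: SessionRecording, starts: np.ndarray) -> dict[str, np.ndarray]:
    """Reference series for the component diagnostics.

    ``speed``: windowed mean treadmill speed (PC1 diagnostic);
    ``force_diff``: windowed mean left-minus-right plate force (PC2).
    """
    _, t_speed, v = session.channel("speed")
    _, t_force, left = session.channel("force_left")
    _, _, right = session.channel("force_right")
    return {
        "speed": windowed_reference(t_speed, v, starts),
        "force_diff": windowed_reference(t_force, left - right, starts),
    }
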
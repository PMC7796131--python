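"""Ground-truth activity labels from treadmill speed.

The recorded speed is smoothed with a zero-phase Butterworth low-pass
(the categorical activity labels themselves cannot be filtered, so the
smoothing is applied to the speed trace before thresholding) and then
cut into stand/walk/run/sprint bands using the subject's manually set
speed thresholds.  Because a noisy or filtered speed never equals
exactly zero, "speed = 0" for standing is implemented as
``|speed| < stand_eps`` (default 0.05 m/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

from .synthetic_data import ACTIVITIES, _activity_codes

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import SubjectProfile

__all__ = [
    "LabelSeries",
    "smooth_speed",
    "label_by_speed",
    "window_label",
    "window_labels",
    "count_transitions",
    "write_labels",
    "read_labels",
]

_ACT = np.array(ACTIVITIES, dtype=object)


@dataclass
class LabelSeries:
    """Per-sample activity labels on the speed channel's time grid."""

    times: np.ndarray
    codes: np.ndarray  # int8, indices into ACTIVITIES

    def __post_init__(self) -> None:
        if len(self.times) != len(self.codes):
            raise ValueError("times and codes must have equal length")

    @property
    def labels(self) -> np.ndarray:
        return _ACT[self.codes]


def smooth_speed(
    times: np.ndarray, speeds: np.ndarray, order: int = 6, cutoff: float = 50.0
) -> np.ndarray:
    """Zero-phase low-pass Butterworth smoothing of the speed trace.

    Forward-backward (``filtfilt``) filtering avoids the group delay a
    causal filter would introduce into the labels; the effective
    magnitude response is the squared Butterworth magnitude.
    """
    fs = 1.0 / float(np.median(np.diff(times)))
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist rate {fs / 2:g} Hz")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(speeds, dtype=float))


def label_by_speed(
    times: np.ndarray,
    speeds: np.ndarray,
    profile: "SubjectProfile",
    stand_eps: float = 0.05,
) -> LabelSeries:
    """Threshold speeds into activity bands (upper bounds inclusive).

    stand: |v| < stand_eps; walk: (0, walk_upper]; run:
    (walk_upper, run_upper]; sprint: above run_upper.
    """
    speeds = np.asarray(speeds, dtype=float)
    if np.any(speeds < 0):
        raise ValueError("speeds must be non-negative")
    return LabelSeries(np.asarray(times, dtype=float), _activity_codes(speeds, profile, stand_eps))


def _majority_with_center_tiebreak(codes: np.ndarray, n_classes: int = 4) -> int:
    counts = np.bincount(codes, minlength=n_classes)
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    if len(winners) == 1:
        return int(winners[0])
    center = int(codes[len(codes) // 2])
    return center if center in winners else int(winners[0])


def window_label(series: LabelSeries, window_start: float, window_len: float) -> str:
    """Majority label of the samples in [start, start+len); ties go to
    the label of the window's center sample."""
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    mask = (series.times >= window_start - 1e-12) & (series.times < window_start + window_len - 1e-12)
    codes = series.codes[mask]
    if codes.size == 0:
        raise ValueError("window contains no samples")
    return ACTIVITIES[_majority_with_center_tiebreak(codes)]


def window_labels(series: LabelSeries, starts: np.ndarray, window_len: float) -> np.ndarray:
    """Vectorised :func:`window_label` over a uniform window grid."""
    fs = 1.0 / float(np.median(np.diff(series.times)))
    n_per = int(round(window_len * fs))
    idx0 = np.round(np.asarray(starts) * fs).astype(int)
    if n_per < 1 or np.any(idx0 < 0) or np.any(idx0 + n_per > series.codes.size):
        raise ValueError("window grid extends beyond the label series")
    windows = series.codes[idx0[:, None] + np.arange(n_per)[None, :]]
    return _ACT[[_majority_with_center_tiebreak(row) for row in windows]]


def count_transitions(codes: np.ndarray) -> int:
    """Number of label changes along a series (chatter metric)."""
    codes = np.asarray(codes)
    return int(np.count_nonzero(codes[1:] != codes[:-1]))


def write_labels(series: LabelSeries, path) -> None:
    """Serialise as a two-column delimited file: time_s, label."""
    import pandas as pd

    pd.DataFrame({"time_s": series.times, "label": series.labels}).to_csv(path, index=False)


def read_labels(path) -> LabelSeries:
    import pandas as pd

    frame = pd.read_csv(path)
    index = {a: i for i, a in enumerate(ACTIVITIES)}
    codes = np.array([index[l] for l in frame["label"]], dtype=np.int8)
    return LabelSeries(frame["time_s"].to_numpy(float), codes)
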
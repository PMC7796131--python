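"""Windowed feature extraction: the 44-feature representation.

Features are computed on a sliding window of 0.5 s with 0.30 s overlap
(step 0.2 s), one row per window:

* ACC  - mean per-sample Euclidean norm of each tri-axial accelerometer
  (8 features),
* FPM / FPSD - mean and sample standard deviation of each vertical
  force plate (2 + 2),
* MF   - median frequency of each sEMG channel's one-sided power
  spectral density, interpolated between spectral bins (8),
* H1/H2/H3 - fractions of sEMG samples lying 0-1, 1-2 and >2 sample
  standard deviations (two-sided) from the window mean (8 x 3).

The full-sensor layout is 8 + 2 + 2 + 8 + 24 = 44 columns; for any
sensor subset the count is 4 x (#sEMG) + (#accel) + 2 x (#plates) —
five features per combined sEMG+accelerometer unit.
Windows are half-open on the right; each multi-rate stream contributes
whatever samples fall inside, with no resampling.  z-scoring is fit on
training folds only and applied unchanged to held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .labelling import LabelSeries, window_labels
from .synthetic_data import ChannelSpec, SessionRecording

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "Normalizer",
    "full_feature_specs",
    "feature_count",
    "sliding_windows",
    "acc_feature",
    "fp_features",
    "median_frequency",
    "histogram_bins",
    "extract_features",
    "fit_normalizer",
    "apply_normalizer",
    "subset_features",
    "concat_feature_matrices",
    "write_feature_matrix",
    "read_feature_matrix",
]

WINDOW_S = 0.5
OVERLAP_S = 0.30

FAMILIES = ("ACC", "FPM", "FPSD", "MF", "H1", "H2", "H3")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column: family plus source channel."""

    feature_id: str
    family: str
    channel_id: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")


def full_feature_specs(channel_specs: Sequence[ChannelSpec]) -> list[FeatureSpec]:
    """Canonical 44-column spec for the full sensor suite.

    Order: ACC per accelerometer, FPM then FPSD per plate, MF per sEMG,
    then H1/H2/H3 grouped per sEMG channel.
    """
    accel = [c for c in channel_specs if c.modality == "accel"]
    plates = [c for c in channel_specs if c.modality == "force_plate"]
    semg = [c for c in channel_specs if c.modality == "semg"]
    specs = [FeatureSpec(f"ACC_{c.channel_id}", "ACC", c.channel_id) for c in accel]
    specs += [FeatureSpec(f"FPM_{c.channel_id}", "FPM", c.channel_id) for c in plates]
    specs += [FeatureSpec(f"FPSD_{c.channel_id}", "FPSD", c.channel_id) for c in plates]
    specs += [FeatureSpec(f"MF_{c.channel_id}", "MF", c.channel_id) for c in semg]
    for c in semg:
        specs += [FeatureSpec(f"{h}_{c.channel_id}", h, c.channel_id) for h in ("H1", "H2", "H3")]
    return specs


def feature_count(n_semg: int, n_accel: int, n_plates: int) -> int:
    """Conservation formula: 4 per sEMG (MF + 3 bins), 1 per
    accelerometer (ACC), 2 per force plate (FPM + FPSD).

    A combined sEMG+accelerometer unit therefore contributes 5
    features, giving 8 x 5 + 2 x 2 = 44 for the full suite.
    """
    return 4 * n_semg + n_accel + 2 * n_plates


@dataclass
class FeatureMatrix:
    """Windows x features table with per-window activity labels."""

    values: np.ndarray  # (n_windows, n_features)
    feature_ids: list[str]
    window_starts: np.ndarray
    labels: np.ndarray  # per-window activity names
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_ids):
            raise ValueError("values shape must be (n_windows, n_features)")
        if len(self.window_starts) != len(self.values) or len(self.labels) != len(self.values):
            raise ValueError("window_starts and labels must match the row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_ids)
        frame.insert(0, "window_start_s", self.window_starts)
        frame.insert(1, "label", self.labels)
        return frame


@dataclass
class Normalizer:
    """Per-feature z-score statistics learned from a training set."""

    feature_ids: list[str]
    means: np.ndarray
    sds: np.ndarray


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------


def sliding_windows(duration: float, window: float = WINDOW_S, overlap: float = OVERLAP_S) -> np.ndarray:
    """Start times of fully contained windows: 0, step, 2*step, ...

    step = window - overlap (0.2 s by default); a trailing partial
    window is dropped.  A 150 s record yields 748 windows.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 <= overlap < window:
        raise ValueError("require 0 <= overlap < window")
    if duration < window:
        return np.empty(0)
    step = window - overlap
    n = int(np.floor((duration - window) / step + 1e-9)) + 1
    return np.arange(n) * step


# ---------------------------------------------------------------------------
# per-window features
# ---------------------------------------------------------------------------


def acc_feature(window: np.ndarray) -> float:
    """Mean per-sample Euclidean norm of a tri-axial window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty accelerometer window")
    return float(np.mean(np.linalg.norm(window, axis=-1)))


def fp_features(window: np.ndarray) -> tuple[float, float]:
    """(mean, sample SD) of a force window; SD of a single sample is 0."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty force window")
    sd = float(np.std(window, ddof=1)) if window.size > 1 else 0.0
    return float(np.mean(window)), sd


def median_frequency(window: np.ndarray, fs: float) -> float:
    """Half-power frequency of a Hann-windowed periodogram.

    Returns the frequency at which the cumulative one-sided PSD reaches
    half the total power, linearly interpolated between spectral bins.
    An all-zero window is defined as 0 Hz.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("median frequency needs at least 2 samples")
    return float(_median_frequency_block(window[None, :], fs)[0])


def _median_frequency_block(windows: np.ndarray, fs: float) -> np.ndarray:
    """Vectorised median frequency over rows of ``windows``."""
    freqs, psd = sps.periodogram(windows, fs=fs, window="hann", axis=-1)
    cum = np.cumsum(psd, axis=-1)
    total = cum[:, -1]
    out = np.zeros(windows.shape[0])
    ok = total > 0
    if not np.any(ok):
        return out
    half = total[ok, None] / 2.0
    cum_ok = cum[ok]
    idx = np.argmax(cum_ok >= half, axis=-1)
    rows = np.arange(cum_ok.shape[0])
    c_hi = cum_ok[rows, idx]
    c_lo = np.where(idx > 0, cum_ok[rows, np.maximum(idx - 1, 0)], 0.0)
    f_hi = freqs[idx]
    f_lo = np.where(idx > 0, freqs[np.maximum(idx - 1, 0)], 0.0)
    frac = np.where(c_hi > c_lo, (half[:, 0] - c_lo) / np.where(c_hi > c_lo, c_hi - c_lo, 1.0), 0.0)
    out[ok] = f_lo + frac * (f_hi - f_lo)
    return out


def histogram_bins(window: np.ndarray) -> tuple[float, float, float]:
    """Amplitude-histogram fractions (H1, H2, H3).

    With m the window mean and s the sample SD, H1 is the fraction of
    samples within 1 SD (two-sided), H2 within (1, 2] SD and H3 beyond
    2 SD.  Fractions are sampling-rate invariant and sum to 1.  A
    zero-SD window is (1, 0, 0) by convention.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty sEMG window")
    h = _histogram_bins_block(window[None, :])
    return float(h[0, 0]), float(h[0, 1]), float(h[0, 2])


def _histogram_bins_block(windows: np.ndarray) -> np.ndarray:
    n = windows.shape[-1]
    means = windows.mean(axis=-1, keepdims=True)
    if n > 1:
        sds = windows.std(axis=-1, ddof=1, keepdims=True)
    else:
        sds = np.zeros_like(means)
    out = np.zeros((windows.shape[0], 3))
    degenerate = sds[:, 0] == 0
    out[degenerate, 0] = 1.0
    ok = ~degenerate
    if np.any(ok):
        z = np.abs(windows[ok] - means[ok]) / sds[ok]
        out[ok, 0] = np.mean(z <= 1.0, axis=-1)
        out[ok, 1] = np.mean((z > 1.0) & (z <= 2.0), axis=-1)
        out[ok, 2] = np.mean(z > 2.0, axis=-1)
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _window_view(times: np.ndarray, values: np.ndarray, starts: np.ndarray, window: float) -> np.ndarray:
    """Stacked per-window sample blocks for a uniform-rate stream."""
    fs = 1.0 / float(np.median(np.diff(times)))
    n_per = int(round(window * fs))
    if n_per < 1:
        raise ValueError(
            f"window of {window} s contains no samples at {fs:g} Hz"
        )
    idx0 = np.round(np.asarray(starts) * fs).astype(int)
    if np.any(idx0 + n_per > len(values)):
        raise ValueError("windows extend beyond the recorded stream")
    idx = idx0[:, None] + np.arange(n_per)[None, :]
    return values[idx]


def extract_features(
    session: SessionRecording,
    specs: Sequence[FeatureSpec],
    label_series: LabelSeries,
    window: float = WINDOW_S,
    overlap: float = OVERLAP_S,
) -> FeatureMatrix:
    """One row per sliding window, one column per :class:`FeatureSpec`.

    Each feature is computed from the source channel's samples falling
    in [start, start + window); rows are labelled by the majority
    activity of the label series in the same interval.
    """
    starts = sliding_windows(session.schedule.duration, window, overlap)
    available = set(session.channel_ids)
    missing = sorted({s.channel_id for s in specs} - available)
    if missing:
        raise KeyError(f"session {session.trial_id} lacks channels: {missing}")

    columns: dict[str, np.ndarray] = {}
    by_channel: dict[str, list[FeatureSpec]] = {}
    for spec in specs:
        by_channel.setdefault(spec.channel_id, []).append(spec)

    for channel_id, ch_specs in by_channel.items():
        ch_spec, times, values = session.channel(channel_id)
        families = {s.family for s in ch_specs}
        if families & {"ACC"}:
            wins = _window_view(times, values, starts, window)  # (n, m, 3)
            columns_for = np.mean(np.linalg.norm(wins, axis=-1), axis=-1)
            columns[f"ACC_{channel_id}"] = columns_for
        if families & {"FPM", "FPSD"}:
            wins = _window_view(times, values, starts, window)
            if "FPM" in families:
                columns[f"FPM_{channel_id}"] = wins.mean(axis=-1)
            if "FPSD" in families:
                columns[f"FPSD_{channel_id}"] = wins.std(axis=-1, ddof=1)
        if families & {"MF", "H1", "H2", "H3"}:
            wins = _window_view(times, values, starts, window)
            if "MF" in families:
                columns[f"MF_{channel_id}"] = _median_frequency_block(wins, ch_spec.sampling_rate)
            if families & {"H1", "H2", "H3"}:
                h = _histogram_bins_block(wins)
                for j, fam in enumerate(("H1", "H2", "H3")):
                    if fam in families:
                        columns[f"{fam}_{channel_id}"] = h[:, j]

    values = np.column_stack([columns[s.feature_id] for s in specs]) if specs else np.empty((len(starts), 0))
    labels = window_labels(label_series, starts, window)
    return FeatureMatrix(
        values=values,
        feature_ids=[s.feature_id for s in specs],
        window_starts=starts,
        labels=labels,
        subject_id=session.subject_id,
        trial_id=session.trial_id,
    )


# ---------------------------------------------------------------------------
# normalisation and reshaping
# ---------------------------------------------------------------------------


def fit_normalizer(fm: FeatureMatrix) -> Normalizer:
    """Learn per-column mean and sample SD from a training matrix."""
    if fm.n_windows < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    means = fm.values.mean(axis=0)
    sds = fm.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [fm.feature_ids[i] for i in zero]
        raise ValueError(f"zero-variance features cannot be z-scored: {names}")
    return Normalizer(list(fm.feature_ids), means, sds)


def apply_normalizer(norm: Normalizer, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply training-fold statistics unchanged to any matrix."""
    if norm.feature_ids != fm.feature_ids:
        raise ValueError("normalizer and feature matrix have different columns")
    return FeatureMatrix(
        values=(fm.values - norm.means) / norm.sds,
        feature_ids=list(fm.feature_ids),
        window_starts=fm.window_starts,
        labels=fm.labels,
        subject_id=fm.subject_id,
        trial_id=fm.trial_id,
    )


def subset_features(fm: FeatureMatrix, feature_ids: Sequence[str]) -> FeatureMatrix:
    """Column subset (e.g. an ablation case) preserving row metadata."""
    index = {fid: i for i, fid in enumerate(fm.feature_ids)}
    missing = [fid for fid in feature_ids if fid not in index]
    if missing:
        raise KeyError(f"features not present: {missing}")
    cols = [index[fid] for fid in feature_ids]
    return FeatureMatrix(
        values=fm.values[:, cols],
        feature_ids=list(feature_ids),
        window_starts=fm.window_starts,
        labels=fm.labels,
        subject_id=fm.subject_id,
        trial_id=fm.trial_id,
    )


def concat_feature_matrices(mats: Sequence[FeatureMatrix]) -> FeatureMatrix:
    if not mats:
        raise ValueError("nothing to concatenate")
    ids = mats[0].feature_ids
    for m in mats[1:]:
        if m.feature_ids != ids:
            raise ValueError("feature matrices have mismatched columns")
    return FeatureMatrix(
        values=np.vstack([m.values for m in mats]),
        feature_ids=list(ids),
        window_starts=np.concatenate([m.window_starts for m in mats]),
        labels=np.concatenate([m.labels for m in mats]),
        subject_id=mats[0].subject_id,
        trial_id="+".join(m.trial_id for m in mats),
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    fm.to_frame().to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path, subject_id: str = "", trial_id: str = "") -> FeatureMatrix:
    frame = pd.read_csv(path, sep="\t")
    feature_ids = [c for c in frame.columns if c not in ("window_start_s", "label")]
    return FeatureMatrix(
        values=frame[feature_ids].to_numpy(float),
        feature_ids=feature_ids,
        window_starts=frame["window_start_s"].to_numpy(float),
        labels=frame["label"].to_numpy(object),
        subject_id=subject_id,
        trial_id=trial_id,
    )
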
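"""On-disk session format: one directory per trial.

Dialect version 1: a YAML ``manifest.yaml`` holding subject, trial,
seed, the command schedule and the channel table (spec fields plus the
data file name), and one delimited file per channel with a header of
``time_s,value`` (scalar streams) or ``time_s,x,y,z`` (accelerometers).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthetic_data import ChannelSpec, CommandSchedule, SessionRecording

__all__ = ["write_session", "read_session", "DIALECT_VERSION"]

DIALECT_VERSION = 1


def write_session(session: SessionRecording, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = []
    for spec, times, values in session.channels:
        fname = f"{spec.channel_id}.csv"
        if values.ndim == 1:
            frame = pd.DataFrame({"time_s": times, "value": values})
        else:
            frame = pd.DataFrame(
                {"time_s": times, "x": values[:, 0], "y": values[:, 1], "z": values[:, 2]}
            )
        frame.to_csv(directory / fname, index=False, float_format="%.6g")
        channels.append(
            {
                "channel_id": spec.channel_id,
                "modality": spec.modality,
                "muscle": spec.muscle,
                "segment": spec.segment,
                "side": spec.side,
                "sampling_rate": spec.sampling_rate,
                "file": fname,
            }
        )
    manifest = {
        "dialect_version": DIALECT_VERSION,
        "subject_id": session.subject_id,
        "trial_id": session.trial_id,
        "rng_seed": session.rng_seed,
        "schedule": [
            {"activity": a, "start_s": float(s), "duration_s": float(d)}
            for a, s, d in session.schedule.commands
        ],
        "channels": channels,
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory


def read_session(directory: str | Path) -> SessionRecording:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("dialect_version") != DIALECT_VERSION:
        raise ValueError(f"unsupported session dialect: {manifest.get('dialect_version')}")
    schedule = CommandSchedule(
        tuple((c["activity"], c["start_s"], c["duration_s"]) for c in manifest["schedule"])
    )
    channels = []
    for entry in manifest["channels"]:
        spec = ChannelSpec(
            channel_id=entry["channel_id"],
            modality=entry["modality"],
            muscle=entry["muscle"],
            segment=entry["segment"],
            side=entry["side"],
            sampling_rate=entry["sampling_rate"],
        )
        frame = pd.read_csv(directory / entry["file"])
        times = frame["time_s"].to_numpy(float)
        if "value" in frame.columns:
            values = frame["value"].to_numpy(float)
        else:
            values = frame[["x", "y", "z"]].to_numpy(float)
        channels.append((spec, times, values))
    return SessionRecording(
        subject_id=manifest["subject_id"],
        trial_id=manifest["trial_id"],
        channels=channels,
        schedule=schedule,
        rng_seed=int(manifest["rng_seed"]),
    )
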
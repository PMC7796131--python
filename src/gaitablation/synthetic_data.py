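"""Synthetic multimodal gait sessions.

Generates treadmill trials that mimic the structure of a self-paced
stand/walk/run/sprint protocol instrumented with eight combined
sEMG+accelerometer units (four muscle sites per leg), two vertical
force plates (one per belt) and a treadmill-speed log.  The signal
models are statistical surrogates, not physiological simulations:
their contract is to reproduce the feature-level contrasts the
downstream analysis exploits --

* treadmill speed follows commanded activity with a first-order lag,
* sEMG amplitude and median frequency grade with activity, with a
  larger walk-to-run contrast at the shank than at the thigh,
* accelerometer stride harmonics grow with speed and are stronger
  distally (shank > thigh),
* ground-reaction forces alternate left/right with double support in
  walking and flight phases in running, and conserve body weight on
  average.

All generators are deterministic given a seed; one session seed fans
out to per-channel sub-seeds through a counter-based scheme so each
channel is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "ACTIVITIES",
    "MUSCLES",
    "MUSCLE_SEGMENT",
    "SIDES",
    "SubjectProfile",
    "CommandSchedule",
    "ChannelSpec",
    "SessionRecording",
    "SemgConfig",
    "AccelConfig",
    "ForceConfig",
    "SimulationConfig",
    "default_profiles",
    "full_channel_specs",
    "generate_schedule",
    "generate_study_schedules",
    "simulate_speed",
    "synthesize_semg",
    "synthesize_accelerometer",
    "synthesize_force_plates",
    "generate_session",
]

#: Activity labels, ordered by increasing speed.
ACTIVITIES: tuple[str, ...] = ("stand", "walk", "run", "sprint")

#: The four instrumented muscles and the leg segment each sits on.
MUSCLE_SEGMENT: dict[str, str] = {
    "gastrocnemius": "shank",
    "tibialis_anterior": "shank",
    "hamstring": "thigh",
    "vastus_medialis": "thigh",
}
MUSCLES: tuple[str, ...] = tuple(MUSCLE_SEGMENT)
SIDES: tuple[str, str] = ("left", "right")

_GRAVITY = 9.81  # m/s^2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject speed thresholds and locomotor parameters.

    ``walk_upper`` and ``run_upper`` delimit the walk and run speed
    bands: walk is (0, walk_upper], run is (walk_upper, run_upper] and
    sprint anything above.  ``preferred_speeds`` maps each activity to
    the steady-state speed the subject settles at; ``response_lag`` is
    the first-order time constant (s) of the speed response to a new
    command; ``stride_frequency_base`` scales the stride (full gait
    cycle) frequency in Hz.
    """

    subject_id: str
    walk_upper: float
    run_upper: float
    preferred_speeds: Mapping[str, float]
    response_lag: float = 1.2
    stride_frequency_base: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.walk_upper < self.run_upper:
            raise ValueError("require 0 < walk_upper < run_upper")
        ps = self.preferred_speeds
        missing = set(ACTIVITIES) - set(ps)
        if missing:
            raise ValueError(f"preferred_speeds missing activities: {sorted(missing)}")
        if ps["stand"] != 0:
            raise ValueError("preferred stand speed must be 0")
        if not 0 < ps["walk"] <= self.walk_upper:
            raise ValueError("preferred walk speed must lie in (0, walk_upper]")
        if not self.walk_upper < ps["run"] <= self.run_upper:
            raise ValueError("preferred run speed must lie in (walk_upper, run_upper]")
        if not ps["sprint"] > self.run_upper:
            raise ValueError("preferred sprint speed must exceed run_upper")
        if self.response_lag <= 0:
            raise ValueError("response_lag must be positive")


@dataclass(frozen=True)
class CommandSchedule:
    """Contiguous, non-overlapping (activity, start, duration) blocks."""

    commands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        t = 0.0
        for activity, start, duration in self.commands:
            if activity not in ACTIVITIES:
                raise ValueError(f"unknown activity {activity!r}")
            if duration <= 0:
                raise ValueError("command duration must be positive")
            if not math.isclose(start, t, abs_tol=1e-9):
                raise ValueError("commands must be contiguous and non-overlapping")
            t = start + duration

    @property
    def duration(self) -> float:
        activity, start, dur = self.commands[-1]
        return start + dur

    @property
    def activities(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.commands)

    def activity_at(self, times: np.ndarray) -> np.ndarray:
        """Commanded activity for each time point (last block extends to end)."""
        starts = np.array([c[1] for c in self.commands])
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, None)
        return np.array([c[0] for c in self.commands], dtype=object)[idx]


@dataclass(frozen=True)
class ChannelSpec:
    """Identity and placement metadata for one recorded stream."""

    channel_id: str
    modality: str  # semg | accel | force_plate | speed
    muscle: str = "none"
    segment: str = "none"
    side: str = "none"
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.modality not in ("semg", "accel", "force_plate", "speed"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality in ("semg", "accel"):
            if self.muscle == "none" or self.segment == "none":
                raise ValueError(f"{self.modality} channels need muscle and segment")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class SessionRecording:
    """One trial's multi-rate raw streams plus metadata.

    ``channels`` maps each :class:`ChannelSpec` to a ``(times, values)``
    pair; ``values`` is 1-D except for accelerometers, which carry an
    ``(n, 3)`` array of x/y/z samples in g.
    """

    subject_id: str
    trial_id: str
    channels: list[tuple[ChannelSpec, np.ndarray, np.ndarray]]
    schedule: CommandSchedule
    rng_seed: int

    def channel(self, channel_id: str) -> tuple[ChannelSpec, np.ndarray, np.ndarray]:
        for entry in self.channels:
            if entry[0].channel_id == channel_id:
                return entry
        raise KeyError(f"no channel {channel_id!r} in session {self.trial_id}")

    @property
    def channel_ids(self) -> list[str]:
        return [spec.channel_id for spec, _, _ in self.channels]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _per_segment_activity(shank: Sequence[float], thigh: Sequence[float]) -> dict:
    return {
        "shank": dict(zip(ACTIVITIES, shank)),
        "thigh": dict(zip(ACTIVITIES, thigh)),
    }


@dataclass
class SemgConfig:
    """Surrogate sEMG model: unit-RMS band-noise carrier x activity gains.

    The carrier blends a 20-150 Hz and a 150-450 Hz band-limited noise;
    ``high_band_weight`` (per segment, per activity) sets the blend and
    hence the median frequency.  ``rms_gain`` (arbitrary amplitude
    units, roughly mV) sets the windowed RMS; the walk->run gain ratio
    is deliberately larger at the shank than at the thigh.
    ``envelope_depth`` modulates amplitude over the gait cycle.
    """

    band_low: tuple[float, float] = (20.0, 150.0)
    band_high: tuple[float, float] = (150.0, 450.0)
    filter_order: int = 4
    rms_gain: dict = field(
        default_factory=lambda: _per_segment_activity(
            shank=(0.05, 0.25, 0.65, 0.85), thigh=(0.05, 0.30, 0.45, 0.55)
        )
    )
    high_band_weight: dict = field(
        default_factory=lambda: _per_segment_activity(
            shank=(0.15, 0.35, 0.65, 0.80), thigh=(0.20, 0.40, 0.50, 0.55)
        )
    )
    envelope_depth: dict = field(
        default_factory=lambda: _per_segment_activity(
            shank=(0.0, 0.45, 0.70, 0.75), thigh=(0.0, 0.30, 0.45, 0.50)
        )
    )


@dataclass
class AccelConfig:
    """Stride-harmonic accelerometer model (units of g).

    Harmonic amplitude is ``speed_gain[segment] * speed``: zero at
    standstill, growing with belt speed, and larger at the shank than
    the thigh (distal points see greater accelerations).  Defaults give
    shank vertical peaks of a few g at running speeds.
    """

    gravity: float = 1.0
    speed_gain: dict = field(default_factory=lambda: {"shank": 0.55, "thigh": 0.22})
    second_harmonic: float = 0.4
    noise_sd: float = 0.03


@dataclass
class ForceConfig:
    """Vertical ground-reaction-force model per plate.

    Stance profiles are weight-normalised so the time-average of
    left+right equals body weight.  Walking uses a duty factor > 0.5
    (double support) and a two-peaked profile; running/sprinting use a
    duty factor < 0.5 (flight phases) and a single peak whose height
    grows as duty shrinks.
    """

    duty: dict = field(default_factory=lambda: {"walk": 0.62, "run": 0.38, "sprint": 0.30})
    walk_dip: float = 0.25  # third-harmonic coefficient -> midstance dip
    sway_amplitude: float = 15.0  # N, quiet-standing sway
    sway_frequency: float = 0.3  # Hz
    noise_sd: float = 8.0  # N, applied only while the plate is loaded
    move_blend_speed: float = 0.3  # m/s, stand->gait blend scale


@dataclass
class SimulationConfig:
    """Study-level defaults: sampling rates, noise levels, body mass."""

    semg_rate: float = 1000.0
    accel_rate: float = 100.0
    force_rate: float = 1000.0
    speed_rate: float = 300.0
    speed_noise_sd: float = 0.05  # m/s, treadmill-speed measurement noise
    stand_eps: float = 0.05  # m/s, |v| below this counts as standing
    body_mass_kg: float = 69.6
    cross_strike_fraction: float = 0.0
    n_commands: int = 15
    command_duration: float = 10.0
    semg: SemgConfig = field(default_factory=SemgConfig)
    accel: AccelConfig = field(default_factory=AccelConfig)
    force: ForceConfig = field(default_factory=ForceConfig)

    @property
    def body_weight_n(self) -> float:
        return self.body_mass_kg * _GRAVITY


_PROFILE_TABLE = [
    # subject_id, walk_upper, run_upper, response_lag, stride_base
    ("S1", 1.3, 2.4, 1.0, 0.95),
    ("S2", 1.6, 3.3, 1.2, 0.90),
    ("S3", 1.6, 2.8, 1.1, 1.00),
    ("S4", 1.4, 2.5, 1.3, 0.92),
    ("S5", 1.2, 2.7, 0.9, 0.98),
]

#: Sprint bands are unbounded above, so the band-midpoint rule cannot
#: apply; default sprint preferred speed sits this far above run_upper.
SPRINT_MARGIN = 0.8


def default_profiles() -> list[SubjectProfile]:
    """Five subject profiles with preferred speeds at threshold-band midpoints."""
    profiles = []
    for sid, walk_upper, run_upper, lag, stride in _PROFILE_TABLE:
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                walk_upper=walk_upper,
                run_upper=run_upper,
                preferred_speeds={
                    "stand": 0.0,
                    "walk": walk_upper / 2.0,
                    "run": (walk_upper + run_upper) / 2.0,
                    "sprint": run_upper + SPRINT_MARGIN,
                },
                response_lag=lag,
                stride_frequency_base=stride,
            )
        )
    return profiles


def full_channel_specs(config: SimulationConfig | None = None) -> list[ChannelSpec]:
    """The canonical 19-channel layout: 8 sEMG + 8 accel + 2 plates + speed."""
    config = config or SimulationConfig()
    specs: list[ChannelSpec] = []
    for muscle in MUSCLES:
        for side in SIDES:
            specs.append(
                ChannelSpec(
                    channel_id=f"semg_{muscle}_{side}",
                    modality="semg",
                    muscle=muscle,
                    segment=MUSCLE_SEGMENT[muscle],
                    side=side,
                    sampling_rate=config.semg_rate,
                )
            )
    for muscle in MUSCLES:
        for side in SIDES:
            specs.append(
                ChannelSpec(
                    channel_id=f"accel_{muscle}_{side}",
                    modality="accel",
                    muscle=muscle,
                    segment=MUSCLE_SEGMENT[muscle],
                    side=side,
                    sampling_rate=config.accel_rate,
                )
            )
    for side in SIDES:
        specs.append(
            ChannelSpec(
                channel_id=f"force_{side}",
                modality="force_plate",
                side=side,
                sampling_rate=config.force_rate,
            )
        )
    specs.append(
        ChannelSpec(channel_id="speed", modality="speed", sampling_rate=config.speed_rate)
    )
    return specs


# ---------------------------------------------------------------------------
# schedule generation
# ---------------------------------------------------------------------------


def _greedy_sequence(
    rng: np.random.Generator, n_commands: int, uncovered: set[tuple[str, str]]
) -> list[str]:
    """Seeded activity sequence preferring transitions not yet covered."""
    outgoing = {a for a, _ in uncovered}
    first_pool = sorted(outgoing) if outgoing else list(ACTIVITIES)
    seq = [first_pool[rng.integers(len(first_pool))]]
    for _ in range(n_commands - 1):
        prev = seq[-1]
        fresh = sorted(b for a, b in uncovered if a == prev)
        pool = fresh if fresh else list(ACTIVITIES)
        nxt = pool[rng.integers(len(pool))]
        seq.append(nxt)
        uncovered.discard((prev, nxt))
    return seq


def generate_schedule(
    order_seed: int,
    n_commands: int = 15,
    duration_per: float = 10.0,
    _uncovered: set[tuple[str, str]] | None = None,
) -> CommandSchedule:
    """Seeded command order for one trial.

    Commands repeat (permutation with repetition); when ``n_commands``
    >= 4 every activity appears at least once.  Passing a shared
    ``_uncovered`` transition set (as :func:`generate_study_schedules`
    does) steers consecutive trials toward transitions not yet seen, so
    a six-trial study covers every ordered activity pair.
    """
    if n_commands < 1:
        raise ValueError("n_commands must be >= 1")
    if duration_per <= 0:
        raise ValueError("duration_per must be positive")
    rng = np.random.default_rng(order_seed)
    uncovered = _uncovered if _uncovered is not None else {
        (a, b) for a in ACTIVITIES for b in ACTIVITIES
    }
    seq = _greedy_sequence(rng, n_commands, uncovered)
    if n_commands >= 4:
        missing = [a for a in ACTIVITIES if a not in seq]
        if missing:  # replace over-represented commands, keep determinism
            counts = {a: seq.count(a) for a in ACTIVITIES}
            for activity in missing:
                donor = max(counts, key=counts.get)
                positions = [i for i, a in enumerate(seq) if a == donor]
                seq[positions[rng.integers(len(positions))]] = activity
                counts[donor] -= 1
                counts[activity] = 1
    commands = tuple(
        (activity, i * duration_per, duration_per) for i, activity in enumerate(seq)
    )
    return CommandSchedule(commands)


def generate_study_schedules(
    seed: int, n_trials: int = 6, n_commands: int = 15, duration_per: float = 10.0
) -> list[CommandSchedule]:
    """Schedules for one subject's trials with even transition coverage.

    Threads a shared uncovered-transition set through the trials so
    that, with the default six trials of fifteen commands, every
    ordered activity pair occurs at least once across the study.
    """
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(n_trials)
    uncovered = {(a, b) for a in ACTIVITIES for b in ACTIVITIES}
    return [
        generate_schedule(int(s), n_commands, duration_per, _uncovered=uncovered)
        for s in trial_seeds
    ]


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------


def _time_grid(duration: float, fs: float) -> np.ndarray:
    n = int(round(duration * fs)) + 1
    return np.arange(n) / fs


def _lag_response(schedule: CommandSchedule, profile: SubjectProfile, times: np.ndarray) -> np.ndarray:
    """Noise-free first-order lag toward each command's preferred speed."""
    tau = profile.response_lag
    v = np.empty_like(times)
    v0 = 0.0
    for i, (activity, start, dur) in enumerate(schedule.commands):
        target = profile.preferred_speeds[activity]
        end = start + dur
        mask = (times >= start - 1e-12) & (
            times <= end + 1e-12 if i == len(schedule.commands) - 1 else times < end - 1e-12
        )
        v[mask] = target + (v0 - target) * np.exp(-(times[mask] - start) / tau)
        v0 = target + (v0 - target) * math.exp(-dur / tau)
    return v


def simulate_speed(
    schedule: CommandSchedule,
    profile: SubjectProfile,
    fs: float,
    seed: int,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-paced treadmill speed: lagged command tracking plus noise.

    The deterministic part is the exact first-order lag response (time
    constant ``profile.response_lag``); zero-mean Gaussian measurement
    noise of standard deviation ``noise_sd`` is added and the result is
    clamped at zero.  ``noise_sd=0`` returns the noise-free response.
    """
    times = _time_grid(schedule.duration, fs)
    v = _lag_response(schedule, profile, times)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, times.size)
    return times, np.clip(v, 0.0, None)


def _activity_codes(speeds: np.ndarray, profile: SubjectProfile, stand_eps: float) -> np.ndarray:
    """0=stand, 1=walk, 2=run, 3=sprint from instantaneous speed."""
    codes = np.zeros(speeds.shape, dtype=np.int8)
    codes[speeds > stand_eps] = 1
    codes[speeds > profile.walk_upper] = 2
    codes[speeds > profile.run_upper] = 3
    return codes


def _stride_frequency(speeds: np.ndarray, profile: SubjectProfile) -> np.ndarray:
    """Stride (full gait cycle) frequency in Hz, rising gently with speed."""
    return profile.stride_frequency_base * (0.7 + 0.3 * speeds)


def _stride_phase(speeds: np.ndarray, profile: SubjectProfile, fs: float) -> np.ndarray:
    """Integrated stride phase in cycles."""
    return np.cumsum(_stride_frequency(speeds, profile)) / fs


def _interp_speed(
    speed_times: np.ndarray, speed_values: np.ndarray, target_times: np.ndarray
) -> np.ndarray:
    return np.interp(target_times, speed_times, speed_values)


def _unit_rms_bandnoise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], order: int
) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = math.sqrt(float(np.mean(x**2)))
    return x / rms if rms > 0 else x


# ---------------------------------------------------------------------------
# per-modality synthesis
# ---------------------------------------------------------------------------


def synthesize_semg(
    speed_times: np.ndarray,
    speed_values: np.ndarray,
    spec: ChannelSpec,
    profile: SubjectProfile,
    seed: int,
    config: SimulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Surrogate sEMG stream for one muscle site.

    A unit-RMS carrier blends low-band (20-150 Hz) and high-band
    (150-450 Hz) Gaussian noise with an activity-dependent weight (the
    median-frequency control), then is scaled by an activity-dependent
    RMS gain and a gait-cycle envelope at the stride frequency.
    """
    if spec.modality != "semg":
        raise ValueError(f"channel {spec.channel_id!r} is not an sEMG channel")
    config = config or SimulationConfig()
    cfg = config.semg
    fs = spec.sampling_rate
    times = _time_grid(float(speed_times[-1]), fs)
    v = _interp_speed(speed_times, speed_values, times)
    codes = _activity_codes(v, profile, config.stand_eps)

    gains = np.array([cfg.rms_gain[spec.segment][a] for a in ACTIVITIES])[codes]
    weights = np.array([cfg.high_band_weight[spec.segment][a] for a in ACTIVITIES])[codes]
    depths = np.array([cfg.envelope_depth[spec.segment][a] for a in ACTIVITIES])[codes]

    if not np.any(gains):
        return times, np.zeros_like(times)

    rng = np.random.default_rng(seed)
    low = _unit_rms_bandnoise(rng, times.size, fs, cfg.band_low, cfg.filter_order)
    high = _unit_rms_bandnoise(rng, times.size, fs, cfg.band_high, cfg.filter_order)
    carrier = np.sqrt(1.0 - weights) * low + np.sqrt(weights) * high

    phase = _stride_phase(v, profile, fs)
    offset = 0.5 if spec.side == "right" else 0.0  # legs alternate by half a cycle
    envelope = 1.0 + depths * np.cos(2.0 * np.pi * (phase + offset))
    envelope /= np.sqrt(1.0 + depths**2 / 2.0)  # keep RMS set by the gain alone

    return times, gains * envelope * carrier


def synthesize_accelerometer(
    speed_times: np.ndarray,
    speed_values: np.ndarray,
    spec: ChannelSpec,
    profile: SubjectProfile,
    seed: int,
    config: SimulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tri-axial accelerometer stream (units of g) for one sensor site.

    Constant gravity on the vertical axis plus stride-frequency
    harmonics whose amplitude grows linearly with belt speed and is
    larger for shank-mounted than thigh-mounted sensors.
    """
    if spec.modality != "accel":
        raise ValueError(f"channel {spec.channel_id!r} is not an accelerometer channel")
    config = config or SimulationConfig()
    cfg = config.accel
    fs = spec.sampling_rate
    times = _time_grid(float(speed_times[-1]), fs)
    v = _interp_speed(speed_times, speed_values, times)

    amplitude = cfg.speed_gain[spec.segment] * v
    phase = 2.0 * np.pi * _stride_phase(v, profile, fs)
    if spec.side == "right":
        phase = phase + np.pi

    z = cfg.gravity + amplitude * (np.sin(phase) + cfg.second_harmonic * np.sin(2 * phase + 0.7))
    x = 0.5 * amplitude * np.sin(phase + 1.1)
    y = 0.3 * amplitude * np.cos(phase)
    xyz = np.column_stack([x, y, z])
    if cfg.noise_sd > 0:
        xyz = xyz + np.random.default_rng(seed).normal(0.0, cfg.noise_sd, xyz.shape)
    return times, xyz


def _stance_shape(u: np.ndarray, dip: float) -> np.ndarray:
    """Within-stance vertical force shape on u in [0, 1), unit-peak-ish."""
    return np.sin(np.pi * u) + dip * np.sin(3.0 * np.pi * u)


def synthesize_force_plates(
    speed_times: np.ndarray,
    speed_values: np.ndarray,
    profile: SubjectProfile,
    seed: int,
    config: SimulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left/right vertical force-plate streams in newtons.

    Standing splits body weight evenly with slow sway; gait alternates
    left/right stance profiles whose duty factor sets double support
    (walking) or flight (running/sprinting).  Profiles are normalised
    so the time-average of left+right equals body weight.  Noise is
    applied only while a plate is loaded so flight phases stay exactly
    zero; forces are clamped non-negative.
    """
    config = config or SimulationConfig()
    cfg = config.force
    fs = config.force_rate
    weight = config.body_weight_n
    times = _time_grid(float(speed_times[-1]), fs)
    v = _interp_speed(speed_times, speed_values, times)
    codes = _activity_codes(v, profile, config.stand_eps)
    rng = np.random.default_rng(seed)

    # per-sample duty factor and dip from the activity; stand values unused
    duty_by_code = np.array(
        [cfg.duty["walk"], cfg.duty["walk"], cfg.duty["run"], cfg.duty["sprint"]]
    )[codes]
    dip_by_code = np.array([cfg.walk_dip, cfg.walk_dip, 0.0, 0.0])[codes]
    # weight-conserving peak scale: mean stance shape is (2/pi)(1 + dip/3)
    mean_shape = (2.0 / np.pi) * (1.0 + dip_by_code / 3.0)
    scale = weight / (2.0 * duty_by_code * mean_shape)

    phase = _stride_phase(v, profile, fs)
    frac_left = np.mod(phase, 1.0)
    frac_right = np.mod(phase + 0.5, 1.0)

    plates = []
    for frac in (frac_left, frac_right):
        in_stance = frac < duty_by_code
        u = np.where(in_stance, frac / duty_by_code, 0.0)
        plates.append(np.where(in_stance, scale * _stance_shape(u, dip_by_code), 0.0))
    left_gait, right_gait = plates

    sway = cfg.sway_amplitude * np.sin(
        2.0 * np.pi * cfg.sway_frequency * times + rng.uniform(0, 2 * np.pi)
    )
    left_stand = weight / 2.0 + sway
    right_stand = weight / 2.0 - sway

    blend = np.clip(v / cfg.move_blend_speed, 0.0, 1.0)
    left = (1.0 - blend) * left_stand + blend * left_gait
    right = (1.0 - blend) * right_stand + blend * right_gait

    if config.cross_strike_fraction > 0:
        cycle = np.floor(phase).astype(np.int64)
        n_cycles = int(cycle.max()) + 1
        swapped = rng.random(n_cycles) < config.cross_strike_fraction
        swap = swapped[cycle] & (blend > 0.5)
        left, right = (
            np.where(swap, right, left),
            np.where(swap, left, right),
        )

    if cfg.noise_sd > 0:
        left = left + rng.normal(0.0, cfg.noise_sd, times.size) * (left > 0)
        right = right + rng.normal(0.0, cfg.noise_sd, times.size) * (right > 0)
    return times, np.clip(left, 0.0, None), np.clip(right, 0.0, None)


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------


def generate_session(
    profile: SubjectProfile,
    trial_id: str,
    config: SimulationConfig | None = None,
    seed: int = 0,
    schedule: CommandSchedule | None = None,
) -> SessionRecording:
    """Compose a full 19-channel session for one trial.

    One session seed fans out to sub-seeds for the schedule, the speed
    noise and each channel, in the fixed canonical channel order, so
    the session is bitwise-reproducible and each channel independently
    so.  All synthesis is driven by the noise-free lag-response speed;
    measurement noise appears only on the recorded speed channel.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s) for s in ss.generate_state(24)]
    if schedule is None:
        schedule = generate_schedule(subseeds[0], config.n_commands, config.command_duration)

    speed_times, v_true = simulate_speed(
        schedule, profile, config.speed_rate, seed=subseeds[1], noise_sd=0.0
    )
    rng_speed = np.random.default_rng(subseeds[2])
    v_measured = v_true.copy()
    if config.speed_noise_sd > 0:
        v_measured = np.clip(
            v_true + rng_speed.normal(0.0, config.speed_noise_sd, v_true.size), 0.0, None
        )

    specs = full_channel_specs(config)
    channels: list[tuple[ChannelSpec, np.ndarray, np.ndarray]] = []
    counter = 3
    for spec in specs:
        if spec.modality == "semg":
            t, x = synthesize_semg(
                speed_times, v_true, spec, profile, seed=subseeds[counter], config=config
            )
            channels.append((spec, t, x))
            counter += 1
        elif spec.modality == "accel":
            t, xyz = synthesize_accelerometer(
                speed_times, v_true, spec, profile, seed=subseeds[counter], config=config
            )
            channels.append((spec, t, xyz))
            counter += 1
    t_force, left, right = synthesize_force_plates(
        speed_times, v_true, profile, seed=subseeds[counter], config=config
    )
    force_specs = [s for s in specs if s.modality == "force_plate"]
    channels.append((force_specs[0], t_force, left))
    channels.append((force_specs[1], t_force, right))
    speed_spec = next(s for s in specs if s.modality == "speed")
    channels.append((speed_spec, speed_times, v_measured))

    return SessionRecording(
        subject_id=profile.subject_id,
        trial_id=trial_id,
        channels=channels,
        schedule=schedule,
        rng_seed=seed,
    )
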
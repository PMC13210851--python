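"""Seeded synthetic smartphone-gait cohorts.

The study dataset (16 participants x 6 goggle conditions, tri-axial pocket
accelerometer at 50 Hz) is not publicly deposited, so this module generates
cohorts with the same statistical structure: stationary pads bracketing an
active walking region, gravity riding on the vertical axis, per-participant
cadence and amplitude variation, and condition-dependent perturbations
(slower cadence, noisier step timing, larger mediolateral sway, per-step
amplitude irregularity) that grow monotonically with the simulated-BAC
severity of the goggle condition.

The gait signal is a sum of two harmonics per axis driven by a common step
phase with jittered step intervals — a statistical emulation, not a
biomechanical model. Axis semantics: x = mediolateral (stride frequency),
y = anteroposterior (step frequency), z = vertical (step frequency,
carrying +9.81 m/s^2 gravity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from ._seeds import derive_seed
from .conditions import (
    CLASS_ORDER,
    ConditionLabel,
    ConditionProfile,
    build_condition_profiles,
    get_condition,
)
from .dataio import (
    ManifestEntry,
    RawRecording,
    SessionManifest,
    TrialMarkers,
    save_manifest,
    write_recording,
)

__all__ = [
    "ParticipantProfile",
    "CohortConfig",
    "Traversal",
    "sample_participant",
    "simulate_traversal",
    "simulate_cohort",
]

GRAVITY = 9.81  # m/s^2 on the vertical (z) axis

# Fixed inter-axis harmonic structure (radians). These are global constants,
# not per-traversal draws: under a null generator (effect_scale=0) traversals
# must differ only through participant identity and exchangeable noise.
_PHASE_Z2 = 0.6
_PHASE_Y = 1.2
_PHASE_Y2 = 2.1
_PHASE_X = 0.4
_HARM2_Z = 0.35  # second-harmonic amplitude ratios
_HARM2_Y = 0.30


@dataclass(frozen=True)
class ParticipantProfile:
    """Stable per-participant gait characteristics."""

    participant_id: str
    base_step_frequency: float  # Hz, ~1.6-2.0
    amplitude_scales: tuple[float, float, float]  # (x, y, z) in m/s^2
    orientation_jitter: float  # std (rad) of the per-traversal pocket rotation

    def __post_init__(self) -> None:
        if self.base_step_frequency <= 0:
            raise ValueError("base_step_frequency must be positive")
        if any(a <= 0 for a in self.amplitude_scales):
            raise ValueError("amplitude_scales must be positive")


@dataclass
class CohortConfig:
    """Everything the cohort generator needs; output is a pure function of this."""

    n_participants: int = 16
    conditions: tuple[str, ...] = CLASS_ORDER
    sampling_rate: float = 50.0
    active_length_range: tuple[int, int] = (2293, 6211)
    active_length_mean: float = 3030.0
    pad_duration: float = 3.0  # seconds of stationary signal at each end
    seed: int = 0
    effect_scale: float = 1.0  # 0 disables all condition effects (null cohort)
    include_gyro: bool = False
    base_step_time_cv: float = 0.025
    sway_noise_base: float = 0.22  # fraction of the mediolateral amplitude
    sensor_noise_std: float = 0.08  # m/s^2, all axes, pads included

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        lo, hi = self.active_length_range
        if lo > hi:
            raise ValueError("active_length_range min must be <= max")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for c in self.conditions:
            get_condition(c)


@dataclass
class Traversal:
    """One simulated walk: recordings, markers, label and ground truth."""

    accelerometer: RawRecording
    markers: TrialMarkers
    label: ConditionLabel
    participant_id: str
    gyroscope: RawRecording | None = None
    truth: dict = field(default_factory=dict)


def sample_participant(participant_id: str, seed: int) -> ParticipantProfile:
    rng = np.random.default_rng(seed)
    return ParticipantProfile(
        participant_id=participant_id,
        base_step_frequency=float(rng.uniform(1.6, 2.0)),
        amplitude_scales=(
            max(float(rng.normal(1.0, 0.15)), 0.5),  # mediolateral
            max(float(rng.normal(1.5, 0.25)), 0.7),  # anteroposterior
            max(float(rng.normal(3.0, 0.45)), 1.5),  # vertical
        ),
        orientation_jitter=0.03,
    )


def _step_phase(rng: np.random.Generator, duration_s: float, step_freq: float,
                cv: float) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative step-boundary times and a callable-free phase description.

    Returns (boundary_times, ...) where the k-th boundary is the time of the
    k-th step onset; the gait phase advances by pi per step interval.
    """
    mean_T = 1.0 / step_freq
    n_steps = int(np.ceil(duration_s * step_freq)) + 4
    intervals = rng.normal(mean_T, cv * mean_T, size=n_steps)
    intervals = np.clip(intervals, 0.3 * mean_T, 2.5 * mean_T)
    boundaries = np.concatenate([[0.0], np.cumsum(intervals)])
    return boundaries, intervals


def _rotation_matrix(rng: np.random.Generator, angle_std: float) -> np.ndarray:
    """Small random rotation emulating pocket-orientation variation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, angle_std)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def simulate_traversal(
    participant: ParticipantProfile,
    condition_profile: ConditionProfile,
    length: int,
    seed: int,
    sampling_rate: float = 50.0,
    pad_duration: float = 3.0,
    base_step_time_cv: float = 0.025,
    sway_noise_base: float = 0.22,
    sensor_noise_std: float = 0.08,
    include_gyro: bool = False,
) -> Traversal:
    """Simulate one traversal (active walking plus stationary pads).

    ``length`` is the number of active-walking samples; the recording is
    padded with ``pad_duration`` seconds of stationary signal on each side
    and the trial markers bracket the active region. Identical arguments
    give identical output.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    rate = sampling_rate
    n_pad = int(round(pad_duration * rate))
    n_total = length + 2 * n_pad

    prof = condition_profile
    step_freq = participant.base_step_frequency * prof.cadence_multiplier
    cv = base_step_time_cv * prof.step_time_cv_multiplier
    duration = length / rate
    t_active = np.arange(length) / rate

    boundaries, _ = _step_phase(rng, duration, step_freq, cv)
    # Phase advances by pi per step; piecewise-linear in time between onsets.
    theta = np.interp(t_active, boundaries, np.arange(len(boundaries)) * np.pi)
    theta = theta + rng.uniform(0.0, 2 * np.pi)  # global shift == time shift

    # Per-step amplitude modulation (gait irregularity).
    step_idx = np.clip(np.searchsorted(boundaries, t_active, side="right") - 1,
                       0, len(boundaries) - 2)
    mod = rng.normal(0.0, max(prof.harmonic_irregularity, 0.0),
                     size=len(boundaries) - 1)
    mod = np.clip(mod, -0.8, 2.0)[step_idx]

    ax_scale, ay_scale, az_scale = participant.amplitude_scales
    x = ax_scale * (1 + mod) * np.sin(theta + _PHASE_X)
    y = ay_scale * ((1 + mod) * np.sin(2 * theta + _PHASE_Y)
                    + _HARM2_Y * np.sin(4 * theta + _PHASE_Y2))
    z = az_scale * ((1 + mod) * np.sin(2 * theta)
                    + _HARM2_Z * np.sin(4 * theta + _PHASE_Z2))

    # Mediolateral sway: low-pass filtered noise, amplified by impairment.
    sway_std = sway_noise_base * prof.sway_amplitude_multiplier * ax_scale
    white = rng.normal(size=length)
    if length > 20:
        b, a = _signal.butter(2, 2.0 / (rate / 2.0))
        sway = _signal.filtfilt(b, a, white)
        sway *= sway_std / max(np.std(sway), 1e-12)
    else:
        sway = white * sway_std
    x = x + sway

    dyn = np.zeros((n_total, 3))
    dyn[n_pad:n_pad + length, 0] = x
    dyn[n_pad:n_pad + length, 1] = y
    dyn[n_pad:n_pad + length, 2] = z
    # Pocket orientation: small fixed rotation of the dynamic component per
    # traversal; gravity stays on z (the simplified-compensation convention
    # downstream subtracts a constant 9.81 from z only).
    R = _rotation_matrix(rng, participant.orientation_jitter)
    dyn = dyn @ R.T
    dyn += rng.normal(0.0, sensor_noise_std, size=dyn.shape)
    dyn[:, 2] += GRAVITY

    # Integer-ms timestamps at a nominal 20 ms with +-1 ms jitter (strictly
    # increasing since consecutive gaps are >= 18 ms).
    ts = np.arange(n_total, dtype=np.int64) * int(round(1000 / rate))
    ts = ts + rng.integers(-1, 2, size=n_total)
    ts[0] = max(ts[0], 0)

    accel = RawRecording("accelerometer", ts, dyn, placement="pocket")
    markers = TrialMarkers(i_start_raw=n_pad, i_stop_raw=n_pad + length - 1)

    gyro = None
    if include_gyro:
        # Format-fidelity only: never consumed by the models.
        g = np.gradient(dyn, axis=0) * rate * 0.05
        gyro = RawRecording("gyroscope", ts.copy(), g, placement="pocket")

    truth = {
        "active_start": n_pad,
        "active_stop": n_pad + length,  # exclusive
        "step_frequency": step_freq,
        "step_boundaries_s": boundaries,
        "step_time_cv": cv,
        "sway_std": sway_std,
    }
    return Traversal(accelerometer=accel, markers=markers,
                     label=prof.label, participant_id=participant.participant_id,
                     gyroscope=gyro, truth=truth)


def _draw_active_lengths(rng: np.random.Generator, n: int,
                         lo: int, hi: int, mean: float) -> np.ndarray:
    """Right-skewed active lengths: truncated exponential above the minimum.

    The scale is solved so the truncated mean matches the configured mean;
    this reproduces min, max and mean simultaneously (a uniform draw on the
    range cannot).
    """
    span = float(hi - lo)
    target = float(mean - lo)
    if span <= 0 or target <= 0:
        return np.full(n, lo, dtype=int)
    # Solve mean of Exp(scale) truncated at span == target by bisection.
    def trunc_mean(s: float) -> float:
        z = span / s
        return s - span * np.exp(-z) / (1 - np.exp(-z))
    s_lo, s_hi = target, span * 10
    for _ in range(80):
        mid = 0.5 * (s_lo + s_hi)
        if trunc_mean(mid) < target:
            s_lo = mid
        else:
            s_hi = mid
    scale = 0.5 * (s_lo + s_hi)
    u = rng.uniform(size=n)
    x = -scale * np.log1p(-u * (1 - np.exp(-span / scale)))
    return (lo + np.round(x)).astype(int)


def simulate_cohort(config: CohortConfig, out_dir: str | Path) -> SessionManifest:
    """Generate a full cohort on disk and return its manifest.

    One traversal per (participant, condition) pair; sensor CSVs are written
    under ``out_dir`` and a ``manifest.yaml`` alongside them. Deterministic
    in ``config`` (including its seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    participants = [
        sample_participant(f"p{i + 1:02d}", derive_seed(config.seed, f"participant:{i}"))
        for i in range(config.n_participants)
    ]
    profiles = {p.label.name: p for p in build_condition_profiles(
        list(config.conditions), effect_scale=config.effect_scale)}

    n_trav = config.n_participants * len(config.conditions)
    len_rng = np.random.default_rng(derive_seed(config.seed, "active-lengths"))
    lo, hi = config.active_length_range
    lengths = _draw_active_lengths(len_rng, n_trav, lo, hi, config.active_length_mean)

    entries: list[ManifestEntry] = []
    k = 0
    for part in participants:
        for cond in config.conditions:
            trav = simulate_traversal(
                part,
                profiles[cond],
                int(lengths[k]),
                seed=derive_seed(config.seed, f"traversal:{part.participant_id}:{cond}"),
                sampling_rate=config.sampling_rate,
                pad_duration=config.pad_duration,
                base_step_time_cv=config.base_step_time_cv,
                sway_noise_base=config.sway_noise_base,
                sensor_noise_std=config.sensor_noise_std,
                include_gyro=config.include_gyro,
            )
            rel_acc = f"{part.participant_id}_{cond}_accelerometer.csv"
            write_recording(trav.accelerometer, out_dir / rel_acc)
            files = {"accelerometer": rel_acc}
            if trav.gyroscope is not None:
                rel_gyr = f"{part.participant_id}_{cond}_gyroscope.csv"
                write_recording(trav.gyroscope, out_dir / rel_gyr)
                files["gyroscope"] = rel_gyr
            entries.append(ManifestEntry(
                participant_id=part.participant_id,
                condition=cond,
                placement="pocket",
                files=files,
                markers=trav.markers,
            ))
            k += 1

    manifest = SessionManifest(
        entries=entries,
        sampling_rate=config.sampling_rate,
        root=out_dir,
        meta={"seed": config.seed, "effect_scale": config.effect_scale,
              "n_participants": config.n_participants,
              "conditions": list(config.conditions)},
    )
    save_manifest(manifest, out_dir / "manifest.yaml")
    return manifest
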
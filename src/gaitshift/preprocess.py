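"""Raw traversal -> uniform-rate, gravity-offset, steady-walking segment.

Stages, in order: synchronise all sensor streams onto one uniform time axis
by linear interpolation; map the raw-axis trial markers onto that axis
(first sample at or after each marker's timestamp); crop to the marked
interval; subtract 9.81 m/s^2 from the vertical channel (simplified gravity
compensation — no orientation normalisation); score windowed periodicity of
the acceleration magnitude by normalised autocorrelation over physiological
stride lags; and keep the span between the first and last valid gait
patterns after trimming a few patterns at each end, so gait initiation and
termination transients are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

from .conditions import ConditionLabel
from .dataio import RawRecording, TrialMarkers
from .synth import GRAVITY

__all__ = [
    "SyncedRecording",
    "SteadySegment",
    "PeriodicityProfile",
    "NoSteadyGaitError",
    "synchronise",
    "map_markers",
    "gravity_offset",
    "periodicity_profile",
    "extract_steady_segment",
    "preprocess_traversal",
]

CHANNEL_NAMES = ("x", "y", "z")


class NoSteadyGaitError(RuntimeError):
    """Too few valid gait patterns to delimit a steady-walking segment."""


@dataclass
class SyncedRecording:
    """Channels aligned on one uniform time axis."""

    rate: float
    time_axis: np.ndarray  # seconds
    channels: np.ndarray  # [T x C]
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __len__(self) -> int:
        return len(self.time_axis)

    def crop(self, i0: int, i1: int) -> "SyncedRecording":
        return SyncedRecording(self.rate, self.time_axis[i0:i1],
                               self.channels[i0:i1], self.channel_names)


@dataclass
class SteadySegment:
    """Steady-locomotion slice of one traversal, gravity-offset on z."""

    values: np.ndarray  # [T x C]
    label: ConditionLabel
    participant_id: str
    bounds: tuple[int, int]  # sample indices on the synced (cropped) axis
    rate: float = 50.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PeriodicityProfile:
    """Windowed autocorrelation periodicity of the acceleration magnitude."""

    window_centres: np.ndarray  # sample indices
    scores: np.ndarray  # in [-1, 1]
    peak_locations: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    threshold: float = 0.4


def synchronise(raw_streams: list[RawRecording] | RawRecording,
                rate: float = 50.0) -> SyncedRecording:
    """Interpolate all streams onto one uniform axis covering their overlap.

    Channels of all streams are concatenated in input order (a single
    accelerometer stream yields the usual three channels).
    """
    if isinstance(raw_streams, RawRecording):
        raw_streams = [raw_streams]
    if not raw_streams:
        raise ValueError("need at least one stream")
    for s in raw_streams:
        if len(s) < 2:
            raise ValueError("each stream needs at least 2 samples")
    t0 = max(s.timestamps_s[0] for s in raw_streams)
    t1 = min(s.timestamps_s[-1] for s in raw_streams)
    if t1 <= t0:
        raise ValueError("streams have empty time overlap")
    n = int(np.floor((t1 - t0) * rate)) + 1
    axis = t0 + np.arange(n) / rate
    cols = []
    for s in raw_streams:
        ts = s.timestamps_s
        for c in range(s.channels.shape[1]):
            cols.append(np.interp(axis, ts, s.channels[:, c]))
    return SyncedRecording(rate=rate, time_axis=axis,
                           channels=np.column_stack(cols))


def map_markers(markers: TrialMarkers, raw_timestamps_s: np.ndarray,
                synced: SyncedRecording) -> tuple[float, float, int, int]:
    """Raw marker indices -> timestamps -> first synced sample at/after each.

    Returns (t_start, t_stop, i_start, i_stop) with i_stop exclusive-ready
    (the synced index of the stop boundary itself).
    """
    markers.validate_against(len(raw_timestamps_s))
    t_start = float(raw_timestamps_s[markers.i_start_raw])
    t_stop = float(raw_timestamps_s[markers.i_stop_raw])
    axis = synced.time_axis
    eps = 0.25 / synced.rate
    i_start = int(np.searchsorted(axis, t_start - eps, side="left"))
    i_stop = int(np.searchsorted(axis, t_stop - eps, side="left"))
    if i_start >= len(axis) or i_stop >= len(axis) or i_start >= i_stop:
        raise ValueError("markers fall outside the synchronised time span")
    return t_start, t_stop, i_start, i_stop


def gravity_offset(synced: SyncedRecording, z_channel: int = 2) -> SyncedRecording:
    """Subtract 9.81 m/s^2 from the vertical channel; others untouched."""
    ch = synced.channels.copy()
    ch[:, z_channel] = ch[:, z_channel] - GRAVITY
    return SyncedRecording(synced.rate, synced.time_axis, ch, synced.channel_names)


def _norm_autocorr_max(mag: np.ndarray, lag_min: int, lag_max: int) -> float:
    m = mag - mag.mean()
    best = -1.0
    w = len(m)
    for lag in range(lag_min, min(lag_max, w - 2) + 1):
        a, b = m[: w - lag], m[lag:]
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        if denom <= 1e-12:
            continue
        r = float((a * b).sum() / denom)
        if r > best:
            best = r
    return best


def periodicity_profile(synced: SyncedRecording, window_s: float = 2.56,
                        lag_range_s: tuple[float, float] = (0.4, 1.5),
                        hop: int | None = None,
                        threshold: float = 0.4,
                        activity_floor: float = 0.2) -> PeriodicityProfile:
    """Sliding-window periodicity of the acceleration magnitude.

    Per window, the score is the maximum normalised autocorrelation of the
    (demeaned) magnitude over lags spanning one physiological stride. Local
    maxima of the score above ``threshold`` are candidate gait patterns; a
    window must additionally carry non-negligible motion energy (magnitude
    std at least ``activity_floor`` times the most active window's) so
    near-stationary noise can never register as gait. Compute after gravity
    offset so the magnitude reflects dynamic acceleration.
    """
    w = int(round(window_s * synced.rate))
    if w > len(synced):
        raise ValueError("window longer than signal")
    if hop is None:
        hop = max(w // 16, 1)
    lag_min = max(int(round(lag_range_s[0] * synced.rate)), 1)
    # Cap lags at half the window so the autocorrelation overlap keeps at
    # least w/2 samples; the magnitude's dominant period is one step
    # (<= ~0.8 s), well inside this cap.
    lag_max = min(int(round(lag_range_s[1] * synced.rate)), w // 2)
    mag = np.linalg.norm(synced.channels, axis=1)
    starts = np.arange(0, len(mag) - w + 1, hop)
    centres = starts + w // 2
    scores = np.array([_norm_autocorr_max(mag[s:s + w], lag_min, lag_max)
                       for s in starts])
    stds = np.array([mag[s:s + w].std() for s in starts])
    active = stds >= activity_floor * stds.max() if len(stds) else stds
    if len(scores) >= 3:
        cand = argrelextrema(scores, np.greater_equal, order=1)[0]
        # greater_equal admits plateaus; drop duplicates and sub-threshold.
        cand = np.array(sorted(set(cand.tolist())), dtype=int)
        peaks = cand[(scores[cand] >= threshold) & active[cand]]
    else:
        peaks = np.nonzero((scores >= threshold) & active)[0]
    return PeriodicityProfile(window_centres=centres, scores=scores,
                              peak_locations=peaks, threshold=threshold)


def extract_steady_segment(synced: SyncedRecording, profile: PeriodicityProfile,
                           label: ConditionLabel, participant_id: str,
                           n_trim: int = 3,
                           min_length: int = 256) -> SteadySegment:
    """Keep the span between the (n_trim+1)-th and (last-n_trim)-th valid
    gait patterns; raise ``NoSteadyGaitError`` when fewer than 2*n_trim+1
    patterns were detected or the remainder is shorter than one window.
    """
    peaks = profile.peak_locations
    if len(peaks) < 2 * n_trim + 1:
        raise NoSteadyGaitError(
            f"only {len(peaks)} valid gait patterns; need {2 * n_trim + 1}"
        )
    first = int(profile.window_centres[peaks[n_trim]])
    last = int(profile.window_centres[peaks[len(peaks) - 1 - n_trim]])
    if last - first < min_length:
        raise NoSteadyGaitError(
            f"steady span {last - first} shorter than minimum {min_length}"
        )
    return SteadySegment(values=synced.channels[first:last],
                         label=label, participant_id=participant_id,
                         bounds=(first, last), rate=synced.rate,
                         channel_names=synced.channel_names)


def preprocess_traversal(accel: RawRecording, markers: TrialMarkers,
                         label: ConditionLabel, participant_id: str,
                         rate: float = 50.0, n_trim: int = 3,
                         window_s: float = 2.56,
                         lag_range_s: tuple[float, float] = (0.4, 1.5),
                         threshold: float = 0.4,
                         min_length: int = 256) -> SteadySegment:
    """Full chain: synchronise, map markers, crop, gravity-offset, extract."""
    synced = synchronise(accel, rate=rate)
    _, _, i_start, i_stop = map_markers(markers, accel.timestamps_s, synced)
    cropped = synced.crop(i_start, i_stop + 1)
    offset = gravity_offset(cropped)
    profile = periodicity_profile(offset, window_s=window_s,
                                  lag_range_s=lag_range_s, threshold=threshold)
    seg = extract_steady_segment(offset, profile, label, participant_id,
                                 n_trim=n_trim, min_length=min_length)
    # Report bounds on the original synced axis for QC.
    seg.bounds = (seg.bounds[0] + i_start, seg.bounds[1] + i_start)
    return seg
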
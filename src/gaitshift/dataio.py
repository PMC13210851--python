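"""Reading and writing acquisition files and session manifests.

The acquisition app stores each sensor's stream in its own four-column CSV:
an integer millisecond timestamp followed by the three sensor axes. A
session manifest (YAML) lists, per traversal, the participant, the goggle
condition, the device placement, the per-sensor file paths and the manually
picked start/stop marker indices on the raw accelerometer axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditions import CLASS_ORDER, get_condition

__all__ = [
    "RawRecording",
    "TrialMarkers",
    "ManifestEntry",
    "SessionManifest",
    "read_recording",
    "write_recording",
    "load_manifest",
    "save_manifest",
    "RecordingFormatError",
]

SENSOR_KINDS = ("accelerometer", "gyroscope")
PLACEMENTS = ("pocket", "wrist")

_CSV_HEADER = ["timestamp_ms", "c1", "c2", "c3"]


class RecordingFormatError(ValueError):
    """A sensor CSV violates the four-column numeric contract."""


@dataclass
class RawRecording:
    """One sensor stream as written by the acquisition app.

    ``timestamps_ms`` are strictly increasing integer milliseconds;
    ``channels`` is a [T x 3] array (m/s^2 for the accelerometer, rad/s for
    the gyroscope).
    """

    sensor_kind: str
    timestamps_ms: np.ndarray
    channels: np.ndarray
    placement: str = "pocket"

    def __post_init__(self) -> None:
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValueError(f"sensor_kind must be one of {SENSOR_KINDS}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")
        self.timestamps_ms = np.asarray(self.timestamps_ms)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 3:
            raise ValueError("channels must be a [T x 3] array")
        if len(self.timestamps_ms) != len(self.channels):
            raise ValueError("timestamps and channels must have equal length")
        if len(self.timestamps_ms) > 1:
            diffs = np.diff(self.timestamps_ms)
            bad = np.nonzero(diffs <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"timestamps must be strictly increasing; first violation at row {bad[0] + 1}"
                )

    def __len__(self) -> int:
        return len(self.timestamps_ms)

    @property
    def timestamps_s(self) -> np.ndarray:
        return np.asarray(self.timestamps_ms, dtype=float) / 1000.0


@dataclass(frozen=True)
class TrialMarkers:
    """Manually picked walking-trial boundaries, as raw-axis sample indices."""

    i_start_raw: int
    i_stop_raw: int

    def __post_init__(self) -> None:
        if not (0 <= self.i_start_raw < self.i_stop_raw):
            raise ValueError("markers must satisfy 0 <= i_start_raw < i_stop_raw")

    def validate_against(self, raw_length: int) -> None:
        if self.i_stop_raw >= raw_length:
            raise ValueError(
                f"i_stop_raw={self.i_stop_raw} outside recording of length {raw_length}"
            )


@dataclass
class ManifestEntry:
    participant_id: str
    condition: str
    placement: str
    files: dict[str, str]  # sensor kind -> path (relative to manifest dir)
    markers: TrialMarkers

    def __post_init__(self) -> None:
        get_condition(self.condition)  # validates the label
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")


@dataclass
class SessionManifest:
    entries: list[ManifestEntry]
    sampling_rate: float = 50.0
    root: Path = field(default_factory=Path)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.participant_id, e.condition)
            if key in seen:
                raise ValueError(f"duplicate (participant, condition) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def path_for(self, entry: ManifestEntry, sensor_kind: str) -> Path:
        return Path(self.root) / entry.files[sensor_kind]


def read_recording(path: str | os.PathLike, sensor_kind: str = "accelerometer",
                   placement: str = "pocket") -> RawRecording:
    """Read one sensor CSV (timestamp_ms plus three axis columns)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:
        raise RecordingFormatError(f"{path}: {exc}") from exc
    if df.shape[1] != 4:
        raise RecordingFormatError(
            f"{path}: expected 4 columns (timestamp + 3 axes), found {df.shape[1]}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise RecordingFormatError(f"{path}: non-numeric value in data row {row}")
    ts = values[:, 0]
    if len(ts) > 1:
        bad = np.nonzero(np.diff(ts) <= 0)[0]
        if bad.size:
            raise RecordingFormatError(
                f"{path}: timestamps not strictly increasing at row {bad[0] + 1}"
            )
    return RawRecording(sensor_kind=sensor_kind, timestamps_ms=ts,
                        channels=values[:, 1:4], placement=placement)


def write_recording(recording: RawRecording, path: str | os.PathLike) -> None:
    """Write a sensor stream as a four-column CSV at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(_CSV_HEADER) + "\n")
        ts = recording.timestamps_ms
        ch = recording.channels
        for i in range(len(ts)):
            fh.write("%d,%.17g,%.17g,%.17g\n" % (int(ts[i]), ch[i, 0], ch[i, 1], ch[i, 2]))


def load_manifest(path: str | os.PathLike, check_files: bool = True) -> SessionManifest:
    """Load and validate a session manifest (YAML)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ValueError(f"{path}: manifest must be a mapping with an 'entries' list")
    entries = []
    for i, raw in enumerate(doc["entries"]):
        missing = {"participant_id", "condition", "placement", "files", "markers"} - set(raw)
        if missing:
            raise ValueError(f"{path}: entry {i} missing keys {sorted(missing)}")
        mk = raw["markers"]
        entries.append(
            ManifestEntry(
                participant_id=str(raw["participant_id"]),
                condition=str(raw["condition"]),
                placement=str(raw["placement"]),
                files={k: str(v) for k, v in raw["files"].items()},
                markers=TrialMarkers(int(mk["i_start_raw"]), int(mk["i_stop_raw"])),
            )
        )
    manifest = SessionManifest(
        entries=entries,
        sampling_rate=float(doc.get("sampling_rate", 50.0)),
        root=path.parent,
        meta=doc.get("meta", {}),
    )
    if check_files:
        for e in manifest.entries:
            for kind, rel in e.files.items():
                p = manifest.path_for(e, kind)
                if not p.exists():
                    raise FileNotFoundError(
                        f"{path}: entry ({e.participant_id}, {e.condition}) references missing file {p}"
                    )
    return manifest


def save_manifest(manifest: SessionManifest, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "sampling_rate": manifest.sampling_rate,
        "meta": manifest.meta,
        "entries": [
            {
                "participant_id": e.participant_id,
                "condition": e.condition,
                "placement": e.placement,
                "files": dict(e.files),
                "markers": {
                    "i_start_raw": int(e.markers.i_start_raw),
                    "i_stop_raw": int(e.markers.i_stop_raw),
                },
            }
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
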
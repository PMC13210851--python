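"""Train/test window datasets.

Each steady segment is first split chronologically (initial 80% train,
final 20% test — the split happens before windowing so no window straddles
the boundary and train and test never share a sample), then each side is cut
into fixed-length sliding windows (256 samples = 5.12 s at 50 Hz, stride 4),
and finally only the training windows are expanded with zero-mean white
Gaussian noise copies (default 10 copies at variance 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import CLASS_ORDER
from .preprocess import SteadySegment

__all__ = [
    "WindowingConfig",
    "WindowDataset",
    "split_traversal",
    "make_windows",
    "augment_with_noise",
    "assemble_dataset",
    "fold_bounds",
    "standardise_datasets",
]


@dataclass
class WindowingConfig:
    window_len: int = 256
    stride: int = 4
    train_fraction: float = 0.8
    noise_variance: float = 0.2
    n_augmented: int = 10  # extra noisy copies per original training window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.n_augmented < 0:
            raise ValueError("n_augmented must be >= 0")

    @property
    def window_duration_s(self) -> float:
        """Window duration in seconds at the acquisition rate (50 Hz)."""
        return self.window_len / 50.0


@dataclass
class WindowDataset:
    """Fixed-length labelled windows with provenance groups.

    ``windows`` is [N x window_len x C] float32; ``labels`` holds class
    indices into ``class_order``; ``groups`` carries one row per window
    (participant, traversal, split, augmented flag).
    """

    windows: np.ndarray
    labels: np.ndarray
    groups: pd.DataFrame
    channel_names: tuple[str, ...]
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if not (len(self.windows) == len(self.labels) == len(self.groups)):
            raise ValueError("windows, labels and groups must align")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def label_names(self) -> np.ndarray:
        return np.asarray(self.class_order)[self.labels]

    def select_channels(self, names: list[str] | tuple[str, ...]) -> "WindowDataset":
        idx = [self.channel_names.index(n) for n in names]
        return WindowDataset(self.windows[:, :, idx], self.labels,
                             self.groups, tuple(names), self.class_order)


def split_traversal(segment: np.ndarray, train_fraction: float = 0.8
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Chronological split at floor(T * fraction); parts are contiguous,
    disjoint and concatenate back to the segment."""
    seg = np.asarray(segment)
    cut = int(np.floor(len(seg) * train_fraction))
    if cut < 1 or cut >= len(seg):
        raise ValueError(f"segment of length {len(seg)} too short to split")
    return seg[:cut], seg[cut:]


def make_windows(series: np.ndarray, window_len: int, stride: int) -> np.ndarray:
    """All windows starting at 0, stride, 2*stride, ...; count is
    floor((T - L) / stride) + 1, or an empty array when T < L."""
    series = np.asarray(series)
    T = len(series)
    if T < window_len:
        return np.empty((0, window_len) + series.shape[1:], dtype=series.dtype)
    starts = np.arange(0, T - window_len + 1, stride)
    return np.stack([series[s:s + window_len] for s in starts])


def augment_with_noise(windows: np.ndarray, variance: float, n_copies: int,
                       seed: int) -> np.ndarray:
    """Originals first, then n_copies noisy replicas each (i.i.d. Gaussian,
    mean 0, the given variance, per sample and channel)."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    windows = np.asarray(windows)
    if n_copies == 0 or len(windows) == 0:
        return windows.copy()
    rng = np.random.default_rng(seed)
    std = float(np.sqrt(variance))
    copies = [windows]
    for _ in range(n_copies):
        copies.append(windows + rng.normal(0.0, std, size=windows.shape
                                           ).astype(windows.dtype, copy=False))
    return np.concatenate(copies, axis=0)


def fold_bounds(T: int, k: int, fold: int) -> tuple[int, int]:
    """Bounds of the ``fold``-th of ``k`` contiguous test chunks of a
    segment of length T (used by k-fold cross-validation)."""
    edges = np.linspace(0, T, k + 1).astype(int)
    return int(edges[fold]), int(edges[fold + 1])


def _window_segment(seg: SteadySegment, cfg: WindowingConfig, seed: int,
                    test_bounds: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Window one segment given explicit test-chunk bounds; returns
    (train_windows, test_windows) with train augmented."""
    vals = seg.values.astype(np.float32)
    t0, t1 = test_bounds
    test_part = vals[t0:t1]
    train_parts = [p for p in (vals[:t0], vals[t1:]) if len(p) >= cfg.window_len]
    train_w = [make_windows(p, cfg.window_len, cfg.stride) for p in train_parts]
    train = (np.concatenate(train_w, axis=0) if train_w
             else np.empty((0, cfg.window_len, vals.shape[1]), np.float32))
    test = make_windows(test_part, cfg.window_len, cfg.stride)
    train = augment_with_noise(train, cfg.noise_variance, cfg.n_augmented, seed)
    return train, test


def assemble_dataset(segments: list[SteadySegment], cfg: WindowingConfig,
                     fold: int | None = None, n_folds: int = 5
                     ) -> tuple[WindowDataset, WindowDataset]:
    """Build the train/test window datasets from preprocessed segments.

    Default: per traversal, the initial 80% trains and the final 20% tests.
    With ``fold`` set, the ``fold``-th contiguous 1/n_folds chunk of every
    traversal tests instead (cross-validation mode). Only training windows
    are noise-augmented; labels come from each segment's traversal.
    """
    if not segments:
        raise ValueError("no segments to assemble")
    channel_names = segments[0].channel_names
    cls = {name: i for i, name in enumerate(CLASS_ORDER)}
    tr_w, tr_y, tr_g, te_w, te_y, te_g = [], [], [], [], [], []
    for ti, seg in enumerate(segments):
        if seg.channel_names != channel_names:
            raise ValueError("segments have mixed channel sets")
        T = len(seg)
        if fold is None:
            cut = int(np.floor(T * cfg.train_fraction))
            bounds = (cut, T)
        else:
            bounds = fold_bounds(T, n_folds, fold)
        train, test = _window_segment(seg, cfg, cfg.seed + ti, bounds)
        y = cls[seg.label.name]
        n_orig = len(train) // (1 + cfg.n_augmented) if cfg.n_augmented else len(train)
        for store_w, store_y, store_g, wins, split in (
            (tr_w, tr_y, tr_g, train, "train"), (te_w, te_y, te_g, test, "test")):
            if len(wins) == 0:
                continue
            store_w.append(wins)
            store_y.append(np.full(len(wins), y, dtype=np.int64))
            aug = np.zeros(len(wins), dtype=bool)
            if split == "train" and cfg.n_augmented:
                aug[n_orig:] = True
            store_g.append(pd.DataFrame({
                "participant": seg.participant_id,
                "traversal": ti,
                "split": split,
                "augmented": aug,
            }))

    def _pack(ws, ys, gs) -> WindowDataset:
        if not ws:
            raise ValueError("no windows produced; segments too short")
        return WindowDataset(
            windows=np.concatenate(ws, axis=0),
            labels=np.concatenate(ys),
            groups=pd.concat(gs, ignore_index=True),
            channel_names=channel_names,
        )

    return _pack(tr_w, tr_y, tr_g), _pack(te_w, te_y, te_g)


def standardise_datasets(train: WindowDataset, test: WindowDataset
                         ) -> tuple[WindowDataset, WindowDataset, np.ndarray,
                                    np.ndarray]:
    """Channel-wise zero-mean/unit-variance scaling fitted on the training
    windows only and applied to both sides; returns (train, test, mu, sd)."""
    mu = train.windows.mean(axis=(0, 1))
    sd = train.windows.std(axis=(0, 1))
    sd = np.where(sd > 1e-8, sd, 1.0)
    def scale(ds: WindowDataset) -> WindowDataset:
        return WindowDataset(((ds.windows - mu) / sd).astype(np.float32),
                             ds.labels, ds.groups, ds.channel_names,
                             ds.class_order)
    return scale(train), scale(test), mu, sd


def assemble_loso(segments: list[SteadySegment], cfg: WindowingConfig,
                  held_out_participant: str
                  ) -> tuple[WindowDataset, WindowDataset]:
    """Leave-one-subject-out split: every window of the held-out
    participant's traversals tests; all other participants' windows train
    (augmented). Provided as an optional protocol; the package makes no
    performance claims under it."""
    participants = {s.participant_id for s in segments}
    if held_out_participant not in participants:
        raise ValueError(f"unknown participant {held_out_participant!r}")
    if len(participants) < 2:
        raise ValueError("need at least 2 participants for a LOSO split")
    channel_names = segments[0].channel_names
    cls = {name: i for i, name in enumerate(CLASS_ORDER)}
    tr_w, tr_y, tr_g, te_w, te_y, te_g = [], [], [], [], [], []
    for ti, seg in enumerate(segments):
        held_out = seg.participant_id == held_out_participant
        wins = make_windows(seg.values.astype(np.float32),
                            cfg.window_len, cfg.stride)
        if len(wins) == 0:
            continue
        if not held_out:
            wins = augment_with_noise(wins, cfg.noise_variance,
                                      cfg.n_augmented, cfg.seed + ti)
        store_w, store_y, store_g = (te_w, te_y, te_g) if held_out else (tr_w, tr_y, tr_g)
        store_w.append(wins)
        store_y.append(np.full(len(wins), cls[seg.label.name], dtype=np.int64))
        store_g.append(pd.DataFrame({
            "participant": seg.participant_id, "traversal": ti,
            "split": "test" if held_out else "train",
            "augmented": np.zeros(len(wins), dtype=bool),
        }))

    def _pack(ws, ys, gs):
        if not ws:
            raise ValueError("no windows produced for one side of the split")
        return WindowDataset(np.concatenate(ws, axis=0), np.concatenate(ys),
                             pd.concat(gs, ignore_index=True), channel_names)

    return _pack(tr_w, tr_y, tr_g), _pack(te_w, te_y, te_g)
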
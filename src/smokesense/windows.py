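"""Sliding-window segmentation and binary smoking labeling.

A recording is cut into fixed-length overlapping windows (default 10 s with a
5 s slide); each window gets a binary label from the ground-truth activity
log: 1 if the fraction of the window covered by smoking-class activities
reaches ``min_overlap_fraction`` (default 0.5; values approaching 0 recover an
"any overlap counts" rule).  Trailing samples that do not fill a window are
dropped so every window has an identical sample count, and windows never
straddle recording (hence subject) boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthio import SMOKING_ACTIVITIES, ActivityLog, SensorRecording

__all__ = ["WindowingConfig", "WindowSet", "segment", "label_windows", "window_count"]


@dataclass(frozen=True)
class WindowingConfig:
    window_length_s: float = 10.0
    slide_s: float = 5.0
    min_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_length_s <= 0 or self.slide_s <= 0:
            raise ValueError("window_length_s and slide_s must be positive")
        if self.slide_s > self.window_length_s:
            raise ValueError("slide_s must not exceed window_length_s")
        if not (0 < self.min_overlap_fraction <= 1):
            raise ValueError("min_overlap_fraction must be in (0, 1]")


@dataclass
class WindowSet:
    """Fixed-length windows of one recording plus (optionally) binary labels.

    ``starts_s`` is an arithmetic sequence with step ``cfg.slide_s``;
    ``sample_slices`` gives each window's [start, stop) sample indices.
    """

    subject_id: str
    cfg: WindowingConfig
    sample_rate_hz: float
    starts_s: np.ndarray  # (n_windows,)
    sample_slices: np.ndarray  # (n_windows, 2) int
    labels: np.ndarray | None = None  # (n_windows,) 0/1 once labeled

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.starts_s):
            raise ValueError("labels length must equal window count")
        lengths = self.sample_slices[:, 1] - self.sample_slices[:, 0]
        if len(lengths) and not np.all(lengths == lengths[0]):
            raise ValueError("all windows must have identical sample counts")

    def __len__(self) -> int:
        return len(self.starts_s)

    @property
    def window_length_s(self) -> float:
        return self.cfg.window_length_s

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.cfg.window_length_s


def window_count(duration_s: float, window_s: float, slide_s: float) -> int:
    """floor((T - W)/S) + 1 for T >= W, else 0."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / slide_s + 1e-9)) + 1


def segment(recording: SensorRecording, cfg: WindowingConfig | None = None) -> WindowSet:
    """Cut a recording into overlapping fixed-length windows (unlabeled).

    Raises ``ValueError`` if the recording is shorter than one window.
    """
    cfg = cfg or WindowingConfig()
    T = recording.duration_s
    if T < cfg.window_length_s:
        raise ValueError(
            f"recording of {T:.1f} s is shorter than one {cfg.window_length_s:.1f} s window"
        )
    n_win = window_count(T, cfg.window_length_s, cfg.slide_s)
    starts = np.arange(n_win) * cfg.slide_s
    fs = recording.sample_rate_hz
    win_n = int(round(cfg.window_length_s * fs))
    start_idx = np.round(starts * fs).astype(np.int64)
    slices = np.stack([start_idx, start_idx + win_n], axis=1)
    return WindowSet(
        subject_id=recording.subject_id,
        cfg=cfg,
        sample_rate_hz=fs,
        starts_s=starts,
        sample_slices=slices,
    )


def _overlap_with_union(
    starts: np.ndarray, ends: np.ndarray, intervals: list[tuple[float, float]]
) -> np.ndarray:
    """Total overlap of each [start, end) window with a union of intervals.

    The intervals come from an ordered non-overlapping log, so per-window
    overlaps simply add.
    """
    total = np.zeros_like(starts, dtype=float)
    for s, e in intervals:
        total += np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0.0, None)
    return total


def label_windows(ws: WindowSet, log: ActivityLog, cfg: WindowingConfig | None = None) -> WindowSet:
    """Assign binary smoking labels from the activity log.

    A window is smoking (1) iff the fraction of its span inside the union of
    smoking-class events is at least ``min_overlap_fraction``.  Windows
    outside all logged events are non-smoking.
    """
    cfg = cfg or ws.cfg
    smoking = log.smoking_intervals()
    overlap = _overlap_with_union(ws.starts_s, ws.ends_s, smoking)
    frac = overlap / cfg.window_length_s
    labels = (frac >= cfg.min_overlap_fraction - 1e-12).astype(np.int8)
    return WindowSet(
        subject_id=ws.subject_id,
        cfg=cfg,
        sample_rate_hz=ws.sample_rate_hz,
        starts_s=ws.starts_s,
        sample_slices=ws.sample_slices,
        labels=labels,
    )
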
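"""Spectrogram imaging of windowed sensor channels.

Each 10 s window of each selected channel is turned into a log-magnitude
short-time Fourier transform image; images are stacked across channels into a
(frequency x time x channel) tensor, the classifier's input.  The default
analysis uses a 512-point FFT with a 256-sample Hamming taper at 95 % overlap
(hop 13), and the resulting raw magnitude array is then conformed to a fixed
256 x 112 image: the redundant Nyquist row of the one-sided 512-point spectrum
is dropped and the time axis is linearly resampled.  The conforming step
exists because a fixed tensor shape is required downstream regardless of the
raw STFT frame count.

IMU channels are featurized identically to sEMG channels and stacked into the
same tensor for fused sensor configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthio import SensorRecording
from .windows import WindowSet

__all__ = [
    "SpectrogramConfig",
    "SpectrogramTensor",
    "ChannelStats",
    "stft_magnitude",
    "conform_shape",
    "featurize",
    "featurize_stack",
    "fit_standardizer",
    "apply_standardizer",
]


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT analysis parameters plus the fixed output image shape."""

    n_fft: int = 512
    stft_window_len: int = 256
    overlap_fraction: float = 0.95
    window_shape: str = "hamming"
    target_freq_bins: int = 256
    target_time_bins: int = 112
    log_magnitude: bool = True
    db_floor: float = -120.0

    def __post_init__(self) -> None:
        if self.stft_window_len > self.n_fft:
            raise ValueError("stft_window_len must not exceed n_fft")
        if self.stft_window_len < 2:
            raise ValueError("stft_window_len must be >= 2")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.target_freq_bins <= 0 or self.target_time_bins <= 0:
            raise ValueError("target dimensions must be positive")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.stft_window_len * (1.0 - self.overlap_fraction))))

    def n_frames(self, signal_len: int) -> int:
        """floor((len - window)/hop) + 1 raw STFT frames (no padding)."""
        if signal_len < self.stft_window_len:
            raise ValueError("signal shorter than the STFT taper")
        return (signal_len - self.stft_window_len) // self.hop + 1


@dataclass
class SpectrogramTensor:
    """One window's stacked per-channel spectrogram image."""

    values: np.ndarray  # (target_freq_bins, target_time_bins, n_channels)
    channel_names: tuple[str, ...]
    window_ref: tuple[str, float]  # (subject_id, start_s)

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != len(self.channel_names):
            raise ValueError("tensor depth must match the channel list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite values")


def stft_magnitude(signal: np.ndarray, cfg: SpectrogramConfig | None = None) -> np.ndarray:
    """One-sided STFT magnitude of a 1-D signal (or a batch on the last axis).

    Returns ``(n_fft//2 + 1, n_frames)`` for 1-D input, with no padding at the
    signal edges; raises if the signal is shorter than the taper.
    """
    cfg = cfg or SpectrogramConfig()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.shape[-1] < cfg.stft_window_len:
        raise ValueError(
            f"signal of {signal.shape[-1]} samples is shorter than the "
            f"{cfg.stft_window_len}-sample STFT taper"
        )
    win = sps.get_window(cfg.window_shape, cfg.stft_window_len, fftbins=True)
    # frame by strided view: frames = floor((len - wlen)/hop) + 1
    n_frames = cfg.n_frames(signal.shape[-1])
    idx = np.arange(cfg.stft_window_len) + cfg.hop * np.arange(n_frames)[:, None]
    frames = signal[..., idx] * win  # (..., n_frames, wlen)
    spec = np.fft.rfft(frames, n=cfg.n_fft, axis=-1)
    mag = np.abs(spec)
    # (..., n_frames, freq) -> (..., freq, n_frames)
    return np.swapaxes(mag, -1, -2)


def _resample_axis(arr: np.ndarray, target: int, axis: int) -> np.ndarray:
    """Linear interpolation of ``arr`` to ``target`` points along ``axis``."""
    n = arr.shape[axis]
    if n == target:
        return arr
    if n == 1:
        return np.repeat(arr, target, axis=axis)
    pos = np.linspace(0.0, n - 1.0, target)
    i0 = np.floor(pos).astype(np.int64)
    i0 = np.minimum(i0, n - 2)
    w = pos - i0
    a0 = np.take(arr, i0, axis=axis)
    a1 = np.take(arr, i0 + 1, axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = target
    w = w.reshape(shape)
    return a0 * (1.0 - w) + a1 * w


def conform_shape(raw: np.ndarray, cfg: SpectrogramConfig | None = None) -> np.ndarray:
    """Map a raw (freq x frames) magnitude array onto the fixed image shape.

    Frequency axis: the one-sided spectrum's redundant Nyquist row is dropped
    when the raw axis is exactly one bin longer than the target (the 257->256
    case); any other size is linearly resampled.  Time axis: always linearly
    resampled to ``target_time_bins``.  Interpolation preserves constants.
    """
    cfg = cfg or SpectrogramConfig()
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("raw spectrogram is empty")
    f_axis, t_axis = raw.ndim - 2, raw.ndim - 1
    if raw.shape[f_axis] == cfg.target_freq_bins + 1:
        raw = np.take(raw, np.arange(cfg.target_freq_bins), axis=f_axis)
    else:
        raw = _resample_axis(raw, cfg.target_freq_bins, axis=f_axis)
    return _resample_axis(raw, cfg.target_time_bins, axis=t_axis)


@dataclass
class ChannelStats:
    """Per-channel standardization statistics (fitted on training data only)."""

    mean: np.ndarray  # (n_channels,)
    sd: np.ndarray  # (n_channels,)
    channel_names: tuple[str, ...]


def _window_matrix(recording: SensorRecording, ws: WindowSet, channel: str) -> np.ndarray:
    x = recording.channel(channel)
    win_n = int(ws.sample_slices[0, 1] - ws.sample_slices[0, 0])
    idx = ws.sample_slices[:, 0][:, None] + np.arange(win_n)
    return x[idx]  # (n_windows, win_n)


def featurize_stack(
    ws: WindowSet,
    recording: SensorRecording,
    channels: tuple[str, ...] | list[str],
    cfg: SpectrogramConfig | None = None,
    stats: ChannelStats | None = None,
) -> np.ndarray:
    """All windows' tensors as one (n_windows, F, T, C) array.

    Channel order follows the given subset order.  Log scaling applies the
    configured dB floor; if ``stats`` is given, per-channel z-scoring is
    applied after log scaling (fit it on training folds only).
    """
    cfg = cfg or SpectrogramConfig()
    channels = tuple(channels)
    if not channels:
        raise ValueError("channel subset must be non-empty")
    known = recording.channel_names
    for ch in channels:
        if ch not in known:
            raise KeyError(f"unknown channel {ch!r}")
    per_channel = []
    for ch in channels:
        mats = _window_matrix(recording, ws, ch)  # (n_win, win_n)
        raw = stft_magnitude(mats, cfg)  # (n_win, freq, frames)
        img = conform_shape(raw, cfg)  # (n_win, F, T)
        if cfg.log_magnitude:
            floor_amp = 10.0 ** (cfg.db_floor / 20.0)
            img = 20.0 * np.log10(np.maximum(img, floor_amp))
        per_channel.append(img)
    out = np.stack(per_channel, axis=-1)  # (n_win, F, T, C)
    if stats is not None:
        out = apply_standardizer(out, stats, channels)
    return out


def featurize(
    ws: WindowSet,
    recording: SensorRecording,
    channels: tuple[str, ...] | list[str],
    cfg: SpectrogramConfig | None = None,
    stats: ChannelStats | None = None,
) -> list[SpectrogramTensor]:
    """One :class:`SpectrogramTensor` per window, in window order."""
    stack = featurize_stack(ws, recording, channels, cfg, stats)
    return [
        SpectrogramTensor(
            values=stack[i],
            channel_names=tuple(channels),
            window_ref=(ws.subject_id, float(ws.starts_s[i])),
        )
        for i in range(stack.shape[0])
    ]


def fit_standardizer(stack: np.ndarray, channel_names: tuple[str, ...]) -> ChannelStats:
    """Per-channel mean/sd over a (n, F, T, C) training stack."""
    mean = stack.mean(axis=(0, 1, 2))
    sd = stack.std(axis=(0, 1, 2))
    sd = np.where(sd > 0, sd, 1.0)
    return ChannelStats(mean=mean, sd=sd, channel_names=tuple(channel_names))


def apply_standardizer(
    stack: np.ndarray, stats: ChannelStats, channels: tuple[str, ...] | None = None
) -> np.ndarray:
    """Apply fitted per-channel z-scoring; channel order must match the fit."""
    if channels is not None and tuple(channels) != tuple(stats.channel_names):
        raise ValueError("channel order differs from the fitted statistics")
    return (stack - stats.mean) / stats.sd
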
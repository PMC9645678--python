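"""Canonical experiment presets.

``run_easy_benchmark`` is the package's end-to-end learning-sanity
experiment: an 8-subject cohort on the compressed ~20-min protocol with
strong gesture gains, featurized with a compact spectrogram image, and
evaluated under LOSO with the default CNN-LSTM for three sensor
configurations (sEMG-only, IMU-only, fused).  The compact 12 x 8 image (a
32-point FFT at 75 % overlap, conformed) keeps the NumPy conv stack fast on
a single CPU while preserving the features that matter at this scale —
broadband sEMG burst energy and low-frequency IMU gesture content; the
full-size 256 x 112 imaging remains the library default.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .evaluate import EvaluationResult, run_experiment
from .net import ModelConfig, TrainConfig
from .spectra import SpectrogramConfig
from .synthio import (
    IMU_CHANNEL_NAMES,
    SEMG_CHANNEL_NAMES,
    GeneratorParams,
    easy_params,
    easy_protocol,
    generate_cohort,
)
from .windows import WindowingConfig

__all__ = [
    "COMPACT_SPECTRO",
    "benchmark_configurations",
    "easy_cohort",
    "run_easy_benchmark",
]

#: Compact spectrogram imaging used by the benchmark experiments.
COMPACT_SPECTRO = SpectrogramConfig(
    n_fft=32,
    stft_window_len=32,
    overlap_fraction=0.75,
    target_freq_bins=12,
    target_time_bins=8,
)


def benchmark_configurations() -> dict[str, tuple[str, ...]]:
    """The three sensor configurations compared by the benchmark."""
    return {
        "sEMG": tuple(SEMG_CHANNEL_NAMES),
        "IMU": tuple(IMU_CHANNEL_NAMES),
        "IMU+sEMG": tuple(SEMG_CHANNEL_NAMES) + tuple(IMU_CHANNEL_NAMES),
    }


def easy_cohort(n_subjects: int = 8, seed: int = 0):
    """Strong-gain cohort on the compressed ten-activity protocol."""
    return generate_cohort(n_subjects, easy_protocol(), easy_params(seed=seed))


def run_easy_benchmark(
    seed: int = 0,
    n_subjects: int = 8,
    configurations: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, EvaluationResult]:
    """LOSO-evaluate the default CNN-LSTM on the easy cohort.

    ``seed`` drives both cohort generation and training.  Returns one
    :class:`EvaluationResult` per configuration.
    """
    cohort = easy_cohort(n_subjects=n_subjects, seed=seed)
    return run_experiment(
        cohort,
        configurations or benchmark_configurations(),
        seed=seed,
        wcfg=WindowingConfig(),
        scfg=COMPACT_SPECTRO,
        mcfg=ModelConfig(),
        tcfg=TrainConfig(seed=seed),
    )
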
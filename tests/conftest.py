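import numpy as np
import pytest

from smokesense.presets import COMPACT_SPECTRO
from smokesense.evaluate import featurize_cohort
from smokesense.synthio import (
    ActivityProtocol,
    GeneratorParams,
    SensorRecording,
    generate_cohort,
)


def make_recording(duration_s: float = 30.0, fs: float = 200.0, seed: int = 0,
                   subject_id: str = "T01") -> SensorRecording:
    """A plain noise recording for segmentation/featurization tests."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    return SensorRecording(
        subject_id=subject_id,
        sample_rate_hz=fs,
        semg=rng.integers(-30, 30, size=(n, 8)).astype(np.int16),
        accel=rng.standard_normal((n, 3)) * 0.02,
        gyro=rng.standard_normal((n, 3)) * 5.0,
    )


def make_mini_protocol() -> ActivityProtocol:
    """Five-activity, two-smoking-session schedule (5.5 min) for fast tests."""
    return ActivityProtocol(
        steps=[
            ("resting", 60.0),
            ("smoking_sitting", 70.0),
            ("eating", 70.0),
            ("walking_slow", 60.0),
            ("smoking_walking_talking", 70.0),
        ],
        n_smoking_sessions=2,
        smoking_session_duration_s=70.0,
    )


@pytest.fixture(scope="session")
def mini_protocol() -> ActivityProtocol:
    return make_mini_protocol()


@pytest.fixture(scope="session")
def mini_params() -> GeneratorParams:
    return GeneratorParams(seed=7)


@pytest.fixture(scope="session")
def mini_cohort(mini_protocol, mini_params):
    return generate_cohort(3, mini_protocol, mini_params)


@pytest.fixture(scope="session")
def mini_dataset(mini_cohort):
    """Featurized mini cohort over a small mixed channel set."""
    channels = ("emg1", "emg3", "emg6", "accel_x", "gyro_x")
    return featurize_cohort(mini_cohort, channels, scfg=COMPACT_SPECTRO)
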
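"""Synthetic sEMG + IMU cohort generation.

This module emulates the structure of an armband-based smoking study: each
subject wears a forearm device recording eight surface-EMG channels (8-bit,
200 Hz) plus a 3-axis accelerometer and 3-axis gyroscope, and performs ten
ordered activities of daily living, four of which are cigarette-smoking
sessions containing periodic hand-to-mouth puff gestures.  Eating is generated
as the hardest confounder: hand-to-mouth kinematics similar to puffing but
with a different sEMG activation profile and faster gesture timing.

The signal model is deliberately simple and fully seeded:

* sEMG channel ``c``: ``round(clip(A_c(t) * n(t)))`` where ``n(t)`` is
  zero-mean Gaussian noise band-passed to 20-95 Hz (unit variance after
  filtering) and ``A_c(t)`` is the baseline noise amplitude, multiplied by
  ``1 + (burst_gain - 1) * w_c`` whenever the activity's activation weight
  ``w_c`` is engaged (during puff/bite gestures for smoking/eating, for the
  whole interval for sustained activities such as phone use).
* accelerometer: the gravity vector rotated by the forearm-pitch trajectory —
  a smooth bump per hand-to-mouth gesture on top of a sustained arm-hold
  offset during smoking and phone use — plus a gait oscillation during
  walking activities, plus white noise.  Units are g.
* gyroscope: the analytic derivative of the pitch trajectory (deg/s) plus
  gait oscillation and white noise.

Every output is a pure function of (protocol, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "ACTIVITIES",
    "SMOKING_ACTIVITIES",
    "EATING_ACTIVITIES",
    "WALKING_ACTIVITIES",
    "GeneratorParams",
    "ActivityProtocol",
    "SensorRecording",
    "ActivityLog",
    "SEMG_CHANNEL_NAMES",
    "IMU_CHANNEL_NAMES",
    "ALL_CHANNEL_NAMES",
    "puff_train",
    "gesture_train",
    "generate_subject",
    "generate_cohort",
    "default_protocol",
    "easy_protocol",
    "easy_params",
]

#: The ten ordered protocol activities, in protocol order.
ACTIVITIES: tuple[str, ...] = (
    "reading",
    "walking_slow",
    "walking_fast",
    "resting",
    "smoking_sitting",
    "phone_talking",
    "eating",
    "smoking_walking_talking",
    "smoking_sitting_talking",
    "smoking_walking_silent",
)

SMOKING_ACTIVITIES = frozenset(a for a in ACTIVITIES if a.startswith("smoking"))
EATING_ACTIVITIES = frozenset({"eating"})
WALKING_ACTIVITIES = frozenset(
    {"walking_slow", "walking_fast", "smoking_walking_talking", "smoking_walking_silent"}
)

SEMG_CHANNEL_NAMES = tuple(f"emg{i}" for i in range(1, 9))
IMU_CHANNEL_NAMES = ("accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z")
ALL_CHANNEL_NAMES = SEMG_CHANNEL_NAMES + IMU_CHANNEL_NAMES


def _default_activation_profiles() -> dict[str, np.ndarray]:
    """Per-activity sEMG activation weights (one weight per channel, in [0,1]).

    Smoking engages a different channel group than eating so that the two
    hand-to-mouth activities are separable from muscle activity alone;
    sustained activities get mild diffuse activations.
    """
    z = np.zeros(8)

    def w(**kw: float) -> np.ndarray:
        out = z.copy()
        for k, v in kw.items():
            out[int(k[1:]) - 1] = v
        return out

    smoking = w(c1=0.9, c3=0.7, c6=1.0, c7=0.5)
    return {
        "reading": w(c2=0.15),
        "walking_slow": z.copy(),
        "walking_fast": z.copy(),
        "resting": z.copy(),
        "smoking_sitting": smoking.copy(),
        "phone_talking": w(c2=0.3, c4=0.25),
        # eating shares channels 3 and 6 with smoking: under per-subject
        # profile jitter the two hand-to-mouth activities are only partly
        # separable from muscle activity alone
        "eating": w(c2=0.8, c3=0.6, c4=0.9, c6=0.5, c8=0.6),
        "smoking_walking_talking": smoking.copy(),
        "smoking_sitting_talking": smoking.copy(),
        "smoking_walking_silent": smoking.copy(),
    }


def _default_posture_pitch() -> dict[str, float]:
    """Sustained forearm-pitch offset (rad) while an activity holds the arm up.

    A smoker keeps the cigarette hand raised between puffs, and phone talking
    holds the phone to the ear: both present a postural cue to the
    accelerometer, making phone use the IMU's confounder the way eating is
    the sEMG's.
    """
    out = {a: 0.35 for a in ACTIVITIES if a.startswith("smoking")}
    out["phone_talking"] = 0.30
    return out


@dataclass
class GeneratorParams:
    """Tunable constants of the synthetic signal model.

    Parameters
    ----------
    sample_rate_hz : float
        Common sampling rate of all channels (device records every channel
        at 200 Hz).
    semg_resolution_bits : int
        sEMG quantization depth; 8 bits gives the signed range [-128, 127].
    puff_duration_s, inter_puff_interval_s : (float, float)
        Uniform ranges for puff length and the gap between puffs.
    bite_duration_s, inter_bite_interval_s : (float, float)
        Same for eating bite gestures (faster, shorter than puffs).
    semg_burst_gain : float
        Multiplicative amplitude increase of a fully-activated channel
        (weight 1) during a gesture, relative to baseline.
    channel_activation_profile : dict[str, ndarray]
        Activity class -> per-channel weights in [0, 1].
    imu_gesture_amplitude : float
        Peak forearm pitch (rad) of the hand-to-mouth bump; scales both the
        accelerometer modulation (g) and the gyroscope peak rate (deg/s).
    baseline_noise_sd : float
        Resting sEMG amplitude in quantization counts.
    placement_rotation_max : float
        Per-subject armband rotation, in channel positions: each subject's
        activation profiles are circularly shifted (with interpolation) by a
        uniform draw from ±this value, emulating electrode placement varying
        from person to person — the main reason sEMG generalizes worse
        across subjects than the IMU does.
    """

    sample_rate_hz: float = 200.0
    semg_resolution_bits: int = 8
    n_semg_channels: int = 8
    puff_duration_s: tuple[float, float] = (2.0, 4.0)
    inter_puff_interval_s: tuple[float, float] = (20.0, 40.0)
    bite_duration_s: tuple[float, float] = (1.0, 2.0)
    inter_bite_interval_s: tuple[float, float] = (8.0, 15.0)
    semg_burst_gain: float = 4.0
    channel_activation_profile: dict[str, np.ndarray] = field(
        default_factory=_default_activation_profiles
    )
    imu_gesture_amplitude: float = 0.7
    bite_amplitude_fraction: float = 0.75
    posture_pitch_rad: dict[str, float] = field(default_factory=_default_posture_pitch)
    posture_ramp_s: float = 3.0
    baseline_noise_sd: float = 3.0
    accel_noise_sd: float = 0.02
    gyro_noise_sd: float = 5.0
    gait_freq_hz: float = 1.8
    gait_accel_amplitude: float = 0.15
    gait_gyro_amplitude: float = 20.0
    semg_band_hz: tuple[float, float] = (20.0, 95.0)
    subject_amp_jitter: float = 0.2
    subject_profile_jitter: float = 0.3
    placement_rotation_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sample_rate_hz",
            "semg_burst_gain",
            "imu_gesture_amplitude",
            "baseline_noise_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("puff_duration_s", "inter_puff_interval_s", "bite_duration_s",
                     "inter_bite_interval_s"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if self.semg_resolution_bits < 2:
            raise ValueError("semg_resolution_bits must be >= 2")
        lo, hi = self.semg_band_hz
        if not (0 < lo < hi < self.sample_rate_hz / 2):
            raise ValueError("semg_band_hz must lie inside (0, Nyquist)")
        for act, w in self.channel_activation_profile.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (self.n_semg_channels,):
                raise ValueError(f"activation profile for {act!r} has wrong length")
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError(f"activation weights for {act!r} must be in [0, 1]")
            self.channel_activation_profile[act] = w
        for act in ("smoking_sitting", "eating"):
            w = self.channel_activation_profile.get(act)
            if w is None or not np.any(w > 0):
                raise ValueError(f"{act!r} needs at least one positive activation weight")

    @property
    def semg_int_range(self) -> tuple[int, int]:
        half = 2 ** (self.semg_resolution_bits - 1)
        return (-half, half - 1)


@dataclass
class ActivityProtocol:
    """Ordered schedule of (activity class, duration in seconds).

    Non-smoking, non-eating activities are capped at 5 min, matching the
    study design this generator emulates.  ``n_smoking_sessions`` and
    ``smoking_session_duration_s`` describe the smoking content and are
    validated against the step list.
    """

    steps: list[tuple[str, float]]
    n_smoking_sessions: int = 4
    smoking_session_duration_s: float = 267.0
    inter_activity_gap_s: float = 0.0

    MAX_NONSMOKING_S = 300.0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("protocol must contain at least one activity")
        n_smoke = 0
        for act, dur in self.steps:
            if dur <= 0:
                raise ValueError(f"duration for {act!r} must be positive")
            if act in SMOKING_ACTIVITIES:
                n_smoke += 1
            elif act not in EATING_ACTIVITIES and dur > self.MAX_NONSMOKING_S:
                raise ValueError(
                    f"non-smoking/non-eating activity {act!r} exceeds "
                    f"{self.MAX_NONSMOKING_S:.0f} s"
                )
        if n_smoke != self.n_smoking_sessions:
            raise ValueError(
                f"protocol has {n_smoke} smoking sessions, "
                f"expected n_smoking_sessions={self.n_smoking_sessions}"
            )
        if self.inter_activity_gap_s < 0:
            raise ValueError("inter_activity_gap_s must be >= 0")

    @property
    def total_duration_s(self) -> float:
        n_gaps = max(0, len(self.steps) - 1)
        return sum(d for _, d in self.steps) + n_gaps * self.inter_activity_gap_s


def default_protocol() -> ActivityProtocol:
    """The full ten-activity schedule (~53 min per subject).

    Four smoking sessions of ~267 s each (the average session length implied
    by 4.75 h of smoking over 64 events), eating extended to 10 min, every
    other activity at the 5-min cap.
    """
    durs = {
        "reading": 300.0,
        "walking_slow": 300.0,
        "walking_fast": 300.0,
        "resting": 300.0,
        "smoking_sitting": 267.0,
        "phone_talking": 300.0,
        "eating": 600.0,
        "smoking_walking_talking": 267.0,
        "smoking_sitting_talking": 267.0,
        "smoking_walking_silent": 267.0,
    }
    return ActivityProtocol(steps=[(a, durs[a]) for a in ACTIVITIES])


def easy_protocol() -> ActivityProtocol:
    """Compressed ten-activity schedule (~23 min per subject) for benchmark runs."""
    durs = {
        "reading": 120.0,
        "walking_slow": 120.0,
        "walking_fast": 120.0,
        "resting": 120.0,
        "smoking_sitting": 150.0,
        "phone_talking": 120.0,
        "eating": 180.0,
        "smoking_walking_talking": 150.0,
        "smoking_sitting_talking": 150.0,
        "smoking_walking_silent": 150.0,
    }
    return ActivityProtocol(
        steps=[(a, durs[a]) for a in ACTIVITIES], smoking_session_duration_s=150.0
    )


def easy_params(seed: int = 0) -> GeneratorParams:
    """Strong-gesture-gain parameter preset: large sEMG bursts, large IMU
    bumps, reduced between-subject jitter.  Intended for learning-sanity
    experiments where the classes should be cleanly separable."""
    return GeneratorParams(
        semg_burst_gain=10.0,
        imu_gesture_amplitude=1.2,
        subject_amp_jitter=0.1,
        subject_profile_jitter=0.35,
        placement_rotation_max=0.5,
        seed=seed,
    )


@dataclass
class SensorRecording:
    """Synchronized multi-channel recording for one subject.

    ``semg`` holds quantized integers in the signed range of the configured
    bit depth; ``accel`` is in g and ``gyro`` in deg/s.  All channel arrays
    share the sample axis.
    """

    subject_id: str
    sample_rate_hz: float
    semg: np.ndarray  # (n_samples, 8) integer
    accel: np.ndarray  # (n_samples, 3) g
    gyro: np.ndarray  # (n_samples, 3) deg/s
    t0: float = 0.0
    semg_resolution_bits: int = 8
    meta: dict = field(default_factory=dict)  # generator details; not serialized

    def __post_init__(self) -> None:
        n = self.semg.shape[0]
        if self.accel.shape[0] != n or self.gyro.shape[0] != n:
            raise ValueError("semg/accel/gyro must share the sample axis")
        if self.semg.ndim != 2 or self.accel.shape[1] != 3 or self.gyro.shape[1] != 3:
            raise ValueError("bad channel array shapes")
        lo, hi = self.semg_int_range
        if self.semg.size and (self.semg.min() < lo or self.semg.max() > hi):
            raise ValueError(
                f"sEMG values outside the {self.semg_resolution_bits}-bit range [{lo}, {hi}]"
            )

    @property
    def semg_int_range(self) -> tuple[int, int]:
        half = 2 ** (self.semg_resolution_bits - 1)
        return (-half, half - 1)

    @property
    def n_samples(self) -> int:
        return self.semg.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def channel_names(self) -> tuple[str, ...]:
        return SEMG_CHANNEL_NAMES[: self.semg.shape[1]] + IMU_CHANNEL_NAMES

    def channel(self, name: str) -> np.ndarray:
        """Return one named channel as float64 (sEMG in counts, IMU in its units)."""
        if name.startswith("emg"):
            idx = int(name[3:]) - 1
            if not 0 <= idx < self.semg.shape[1]:
                raise KeyError(name)
            return self.semg[:, idx].astype(np.float64)
        if name in IMU_CHANNEL_NAMES:
            i = IMU_CHANNEL_NAMES.index(name)
            arr = self.accel if i < 3 else self.gyro
            return arr[:, i % 3].astype(np.float64)
        raise KeyError(name)


@dataclass
class ActivityLog:
    """Ordered, non-overlapping labeled intervals (class, start_s, end_s)."""

    events: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for act, start, end in self.events:
            if end <= start:
                raise ValueError(f"event {act!r}: end {end} <= start {start}")
            if start < prev_end:
                raise ValueError(f"event {act!r} overlaps the previous event")
            prev_end = end

    def intervals(self, classes: frozenset[str] | set[str]) -> list[tuple[float, float]]:
        return [(s, e) for a, s, e in self.events if a in classes]

    def smoking_intervals(self) -> list[tuple[float, float]]:
        return self.intervals(SMOKING_ACTIVITIES)

    @property
    def span(self) -> tuple[float, float]:
        return (self.events[0][1], self.events[-1][2])


def gesture_train(
    start_s: float,
    end_s: float,
    duration_range: tuple[float, float],
    interval_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Sequential gesture intervals inside [start_s, end_s).

    The first gesture begins at the session start; each gesture's duration is
    drawn uniformly from ``duration_range`` and the following gap from
    ``interval_range``.  A gesture that would overrun the session end is
    dropped, so a session shorter than one minimal gesture yields an empty
    list.
    """
    if end_s <= start_s:
        return []
    out: list[tuple[float, float]] = []
    t = start_s
    while True:
        d = rng.uniform(*duration_range)
        if t + d > end_s:
            break
        out.append((t, t + d))
        t += d + rng.uniform(*interval_range)
    return out


def puff_train(
    session_start_s: float,
    session_end_s: float,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Non-overlapping puff intervals inside one smoking session."""
    if session_end_s < session_start_s:
        raise ValueError("session_end_s must be >= session_start_s")
    return gesture_train(
        session_start_s, session_end_s, params.puff_duration_s,
        params.inter_puff_interval_s, rng,
    )


def _rotate_profile(w: np.ndarray, shift: float) -> np.ndarray:
    """Circularly shift a per-channel profile by a fractional channel count."""
    k = int(np.floor(shift))
    f = shift - k
    return (1.0 - f) * np.roll(w, k) + f * np.roll(w, k + 1)


def _bandpassed_unit_noise(
    n: int, n_ch: int, band: tuple[float, float], fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian noise band-passed to ``band`` and rescaled to unit sd."""
    white = rng.standard_normal((n, n_ch))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white, axis=0)
    sd = shaped.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _pitch_bump(t: np.ndarray, start: float, end: float, peak: float) -> np.ndarray:
    """Raised-cosine pitch bump: 0 at the gesture edges, ``peak`` rad mid-gesture."""
    mask = (t >= start) & (t < end)
    out = np.zeros_like(t)
    out[mask] = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[mask] - start) / (end - start)))
    return out


def _pitch_bump_rate(t: np.ndarray, start: float, end: float, peak: float) -> np.ndarray:
    """Analytic time derivative of :func:`_pitch_bump` (rad/s)."""
    mask = (t >= start) & (t < end)
    out = np.zeros_like(t)
    w = 2.0 * np.pi / (end - start)
    out[mask] = peak * 0.5 * w * np.sin(w * (t[mask] - start))
    return out


def generate_subject(
    protocol: ActivityProtocol,
    params: GeneratorParams,
    subject_id: str,
    rng: np.random.Generator | None = None,
) -> tuple[SensorRecording, ActivityLog]:
    """Simulate one subject's full recording plus its ground-truth log.

    ``rng`` defaults to a generator seeded from ``params.seed``; cohort
    generation passes per-subject generators spawned from the master seed.
    Per-subject variation (amplitude and activation-profile jitter) is drawn
    first from ``rng`` so that two different sub-seeds give different, and the
    same sub-seed bitwise-identical, recordings.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    total_s = protocol.total_duration_s
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    # per-subject variation: amplitude scale, per-channel profile attenuation,
    # and armband rotation (circular shift of the activation profiles)
    amp_jit = rng.uniform(1.0 - params.subject_amp_jitter, 1.0 + params.subject_amp_jitter)
    prof_jit = rng.uniform(
        1.0 - params.subject_profile_jitter, 1.0, size=params.n_semg_channels
    )
    rotation = rng.uniform(-params.placement_rotation_max, params.placement_rotation_max)
    eff_profiles = {
        act: _rotate_profile(np.asarray(w), rotation) * prof_jit
        for act, w in params.channel_activation_profile.items()
    }

    # lay out the activity timeline
    events: list[tuple[str, float, float]] = []
    cursor = 0.0
    for i, (act, dur) in enumerate(protocol.steps):
        if i > 0:
            cursor += protocol.inter_activity_gap_s
        events.append((act, cursor, cursor + dur))
        cursor += dur
    log = ActivityLog(events=events)

    # gesture intervals: puffs inside smoking sessions, bites inside eating
    gestures: list[tuple[float, float, str, float]] = []  # (start, end, activity, amp_frac)
    for act, start, end in events:
        if act in SMOKING_ACTIVITIES:
            for g0, g1 in gesture_train(
                start, end, params.puff_duration_s, params.inter_puff_interval_s, rng
            ):
                gestures.append((g0, g1, act, 1.0))
        elif act in EATING_ACTIVITIES:
            for g0, g1 in gesture_train(
                start, end, params.bite_duration_s, params.inter_bite_interval_s, rng
            ):
                gestures.append((g0, g1, act, params.bite_amplitude_fraction))

    # ---- sEMG ----------------------------------------------------------
    unit = _bandpassed_unit_noise(n, params.n_semg_channels, params.semg_band_hz, fs, rng)
    weight = np.zeros((n, params.n_semg_channels))
    zero_w = np.zeros(params.n_semg_channels)
    for act, start, end in events:
        if act in SMOKING_ACTIVITIES or act in EATING_ACTIVITIES:
            continue  # gesture-driven, handled below
        w = eff_profiles.get(act, zero_w)
        sl = slice(int(round(start * fs)), int(round(end * fs)))
        weight[sl] = np.maximum(weight[sl], w)
    for g0, g1, act, _amp in gestures:
        w = eff_profiles[act]
        sl = slice(int(round(g0 * fs)), int(round(g1 * fs)))
        weight[sl] = np.maximum(weight[sl], w)

    amplitude = params.baseline_noise_sd * (
        1.0 + (params.semg_burst_gain * amp_jit - 1.0) * weight
    )
    lo, hi = params.semg_int_range
    semg = np.clip(np.round(amplitude * unit), lo, hi).astype(np.int16)

    # ---- IMU -----------------------------------------------------------
    # sustained arm-hold posture (trapezoidal pitch offset) per activity
    posture = np.zeros(n)
    for act, start, end in events:
        peak = params.posture_pitch_rad.get(act, 0.0) * amp_jit
        if peak <= 0:
            continue
        ramp = min(params.posture_ramp_s, 0.499 * (end - start))
        posture += np.interp(
            t, [start, start + ramp, end - ramp, end], [0.0, peak, peak, 0.0],
            left=0.0, right=0.0,
        )
    pitch = posture.copy()
    pitch_rate = np.gradient(posture) * fs
    for g0, g1, _act, amp_frac in gestures:
        peak = params.imu_gesture_amplitude * amp_frac * amp_jit
        pitch += _pitch_bump(t, g0, g1, peak)
        pitch_rate += _pitch_bump_rate(t, g0, g1, peak)

    gait = np.zeros(n)
    for act, start, end in events:
        if act in WALKING_ACTIVITIES:
            speed = 1.15 if act == "walking_fast" else 1.0
            mask = (t >= start) & (t < end)
            gait[mask] = np.sin(2.0 * np.pi * params.gait_freq_hz * speed * t[mask])

    accel = np.empty((n, 3))
    accel[:, 0] = np.sin(pitch) + 0.6 * params.gait_accel_amplitude * gait
    accel[:, 1] = 0.3 * params.gait_accel_amplitude * gait
    accel[:, 2] = np.cos(pitch) + params.gait_accel_amplitude * gait
    accel += params.accel_noise_sd * rng.standard_normal((n, 3))

    gyro = np.empty((n, 3))
    gyro[:, 0] = np.degrees(pitch_rate) + 0.5 * params.gait_gyro_amplitude * gait
    gyro[:, 1] = 0.3 * np.degrees(pitch_rate) + params.gait_gyro_amplitude * gait
    gyro[:, 2] = 0.2 * params.gait_gyro_amplitude * gait
    gyro += params.gyro_noise_sd * rng.standard_normal((n, 3))

    rec = SensorRecording(
        subject_id=subject_id,
        sample_rate_hz=fs,
        semg=semg,
        accel=accel,
        gyro=gyro,
        semg_resolution_bits=params.semg_resolution_bits,
        meta={
            "effective_profiles": eff_profiles,
            "placement_rotation": rotation,
            "amplitude_scale": amp_jit,
            "gestures": gestures,
        },
    )
    return rec, log


def cohort_seeds(master_seed: int, n_subjects: int) -> list[np.random.Generator]:
    """Deterministic per-subject generators spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_subjects)]


def generate_cohort(
    n_subjects: int,
    protocol: ActivityProtocol,
    params: GeneratorParams,
) -> list[tuple[SensorRecording, ActivityLog]]:
    """Simulate a cohort with unique subject ids and per-subject variation.

    Leave-one-subject-out evaluation needs at least two subjects.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs n_subjects >= 2 (LOSO requires it)")
    out = []
    for i, rng in enumerate(cohort_seeds(params.seed, n_subjects)):
        sid = f"S{i + 1:02d}"
        out.append(generate_subject(protocol, params, sid, rng))
    return out
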
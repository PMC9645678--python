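"""On-disk formats: sensor streams, activity logs, manifests, window-tensor
containers, model checkpoints, and evaluation reports.

Streams and logs are delimited text.  A recording file starts with ``#``
header lines declaring the channel layout and sample rate, followed by one
row per sample: timestamp (seconds from recording start), the sEMG integer
columns, three accelerometer columns (g) and three gyroscope columns (deg/s).
An activity log is ``activity,start_s,end_s`` rows, the dialect of a simple
time-tracker export.  Readers reject malformed input (naming the offending
line) rather than silently truncating.

Window tensors go into a chunked HDF5 container with the featurization config
echoed into a sidecar JSON manifest; reports are written as structured JSON
plus a rendered table.  Report writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .evaluate import ConfusionMatrix, EvaluationResult, FeaturizedDataset, Metrics, metrics
from .net import CnnLstm, ModelConfig, TrainConfig
from .synthio import ACTIVITIES, ActivityLog, SensorRecording

__all__ = [
    "FormatError",
    "DatasetManifest",
    "write_recording",
    "read_recording",
    "write_activity_log",
    "read_activity_log",
    "write_manifest",
    "read_manifest",
    "write_window_tensors",
    "read_window_tensors",
    "save_model",
    "load_model",
    "write_report",
    "read_report",
    "render_report_table",
    "write_sfs_trace",
]

FORMAT_VERSION = "1"
IMU_DECIMALS = 6


class FormatError(ValueError):
    """Malformed on-disk artifact."""


# ---------------------------------------------------------------------------
# sensor streams
# ---------------------------------------------------------------------------


def write_recording(recording: SensorRecording, path: str | Path) -> None:
    path = Path(path)
    n_emg = recording.semg.shape[1]
    cols = (
        ["t"]
        + [f"emg{i}" for i in range(1, n_emg + 1)]
        + ["accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z"]
    )
    header = (
        f"# smokesense-recording v{FORMAT_VERSION}\n"
        f"# subject_id: {recording.subject_id}\n"
        f"# sample_rate_hz: {recording.sample_rate_hz!r}\n"
        f"# semg_resolution_bits: {recording.semg_resolution_bits}\n"
        f"# n_semg_channels: {n_emg}\n"
        f"# t0: {recording.t0!r}\n"
        f"# columns: {','.join(cols)}\n"
    )
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    data = np.column_stack(
        [t, recording.semg.astype(np.float64), recording.accel, recording.gyro]
    )
    fmt = ["%.4f"] + ["%d"] * n_emg + [f"%.{IMU_DECIMALS}f"] * 6
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt, delimiter=",")


def _parse_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta, n_header


def read_recording(path: str | Path) -> SensorRecording:
    """Parse a stream file; raises :class:`FormatError` naming the bad line."""
    path = Path(path)
    meta, n_header = _parse_header(path)
    required = ("subject_id", "sample_rate_hz", "semg_resolution_bits", "n_semg_channels")
    for key in required:
        if key not in meta:
            raise FormatError(f"{path}: header is missing {key!r}")
    n_emg = int(meta["n_semg_channels"])
    bits = int(meta["semg_resolution_bits"])
    n_cols = 1 + n_emg + 6
    try:
        df = pd.read_csv(path, comment="#", header=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no data rows") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged row ({exc})") from None
    if df.shape[1] != n_cols:
        raise FormatError(
            f"{path}: line {n_header + 1}: expected {n_cols} columns "
            f"({n_emg} sEMG declared), found {df.shape[1]}"
        )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: line {n_header + bad + 1}: ragged or non-numeric row")
    semg = df.iloc[:, 1 : 1 + n_emg].to_numpy()
    if not np.allclose(semg, np.round(semg)):
        bad = int(np.argmax(~np.all(np.isclose(semg, np.round(semg)), axis=1)))
        raise FormatError(f"{path}: line {n_header + bad + 1}: non-integer sEMG value")
    semg = semg.astype(np.int16)
    half = 2 ** (bits - 1)
    if semg.min() < -half or semg.max() > half - 1:
        bad = int(np.argmax(np.any((semg < -half) | (semg > half - 1), axis=1)))
        raise FormatError(
            f"{path}: line {n_header + bad + 1}: sEMG value outside "
            f"[{-half}, {half - 1}] for {bits}-bit depth"
        )
    imu = df.iloc[:, 1 + n_emg :].to_numpy(dtype=np.float64)
    return SensorRecording(
        subject_id=meta["subject_id"],
        sample_rate_hz=float(meta["sample_rate_hz"]),
        semg=semg,
        accel=imu[:, :3],
        gyro=imu[:, 3:],
        t0=float(meta.get("t0", "0.0")),
        semg_resolution_bits=bits,
    )


# ---------------------------------------------------------------------------
# activity logs
# ---------------------------------------------------------------------------


def write_activity_log(log: ActivityLog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("activity,start_s,end_s\n")
        for act, start, end in log.events:
            fh.write(f"{act},{start!r},{end!r}\n")


def read_activity_log(path: str | Path) -> ActivityLog:
    """Parse ``activity,start_s,end_s`` rows; events are returned sorted.

    Unknown activity classes warn and pass through (they count as
    non-smoking); an event with end <= start, or overlapping events, raise
    :class:`FormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty activity log") from None
    expected = ["activity", "start_s", "end_s"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    events = []
    for i, row in df.iterrows():
        act = str(row["activity"])
        try:
            start, end = float(row["start_s"]), float(row["end_s"])
        except (TypeError, ValueError):
            raise FormatError(f"{path}: line {i + 2}: non-numeric interval") from None
        if end <= start:
            raise FormatError(f"{path}: line {i + 2}: end {end} <= start {start}")
        if act not in ACTIVITIES:
            warnings.warn(
                f"{path}: unknown activity class {act!r} (treated as non-smoking)",
                stacklevel=2,
            )
        events.append((act, start, end))
    events.sort(key=lambda e: e[1])
    try:
        return ActivityLog(events=events)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------


class DatasetManifest:
    """List of (subject_id, recording_path, log_path) with a format version."""

    def __init__(self, entries: list[dict[str, str]], format_version: str = FORMAT_VERSION):
        ids = [e["subject_id"] for e in entries]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate subject_ids in manifest")
        self.entries = entries
        self.format_version = format_version

    def __len__(self) -> int:
        return len(self.entries)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    payload = {"format_version": manifest.format_version, "recordings": manifest.entries}
    _atomic_write_text(Path(path), json.dumps(payload, indent=2) + "\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    entries = payload.get("recordings", [])
    base = path.parent
    for e in entries:
        for key in ("recording_path", "log_path"):
            p = base / e[key] if not os.path.isabs(e[key]) else Path(e[key])
            if not p.exists():
                raise FormatError(f"{path}: missing file {e[key]!r} for {e['subject_id']}")
    return DatasetManifest(entries, payload.get("format_version", FORMAT_VERSION))


def load_cohort(manifest: DatasetManifest, base: str | Path = ".") -> list:
    base = Path(base)
    out = []
    for e in manifest.entries:
        rec = read_recording(base / e["recording_path"])
        log = read_activity_log(base / e["log_path"])
        out.append((rec, log))
    return out


# ---------------------------------------------------------------------------
# window tensors (chunked binary container + sidecar manifest)
# ---------------------------------------------------------------------------


def write_window_tensors(
    dataset: FeaturizedDataset, path: str | Path, config_echo: Mapping | None = None
) -> None:
    path = Path(path)
    n = dataset.X.shape[0]
    with h5py.File(path, "w") as h5:
        chunk = (min(64, max(1, n)),) + dataset.X.shape[1:]
        h5.create_dataset("X", data=dataset.X, chunks=chunk, compression="gzip",
                          compression_opts=1)
        h5.create_dataset("labels", data=dataset.labels.astype(np.int8))
        sid = np.array([s.encode() for s in dataset.subject_ids])
        h5.create_dataset("subject_ids", data=sid)
        h5.create_dataset("starts_s", data=dataset.starts_s)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "n_windows": int(n),
        "shape": list(dataset.X.shape[1:]),
        "channel_names": list(dataset.channel_names),
        "config": dict(config_echo or {}),
    }
    _atomic_write_text(path.with_suffix(path.suffix + ".json"),
                       json.dumps(sidecar, indent=2) + "\n")


def read_window_tensors(path: str | Path) -> FeaturizedDataset:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    with h5py.File(path, "r") as h5:
        X = h5["X"][...]
        labels = h5["labels"][...]
        subject_ids = np.array([s.decode() for s in h5["subject_ids"][...]], dtype=object)
        starts = h5["starts_s"][...]
    if X.shape[0] != sidecar["n_windows"]:
        raise FormatError(f"{path}: container/sidecar window-count mismatch")
    return FeaturizedDataset(
        X=X, labels=labels, subject_ids=subject_ids, starts_s=starts,
        channel_names=tuple(sidecar["channel_names"]),
    )


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------


def save_model(model: CnnLstm, path: str | Path) -> None:
    """Checkpoint parameters plus full config provenance."""
    path = Path(path)
    np.savez(path, **model.state_arrays())
    meta = {
        "input_shape": list(model.input_shape),
        "seed": model.seed,
        "model_config": model.cfg.__dict__ | {
            "conv_feature_maps": list(model.cfg.conv_feature_maps)
        },
        "train_config": model.train_config.__dict__ if model.train_config else None,
        "fold_id": model.fold_id,
        "loss_history": model.loss_history,
    }
    real = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    _atomic_write_text(real.with_suffix(".json"), json.dumps(meta, indent=2) + "\n")


def load_model(path: str | Path) -> CnnLstm:
    path = Path(path)
    real = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    with open(real.with_suffix(".json")) as fh:
        meta = json.load(fh)
    mc = dict(meta["model_config"])
    mc["conv_feature_maps"] = tuple(mc["conv_feature_maps"])
    model = CnnLstm(tuple(meta["input_shape"]), ModelConfig(**mc), seed=meta["seed"])
    with np.load(real) as state:
        model.load_state_arrays({k: state[k] for k in state.files})
    if meta.get("train_config"):
        model.train_config = TrainConfig(**meta["train_config"])
    model.loss_history = list(meta.get("loss_history", []))
    model.fold_id = meta.get("fold_id")
    return model


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------


def _metrics_dict(m: Metrics) -> dict:
    return {"recall": m.recall, "precision": m.precision, "f1": m.f1,
            "accuracy": m.accuracy, "degenerate": m.degenerate}


def _result_dict(r: EvaluationResult) -> dict:
    return {
        "label": r.label,
        "channels": list(r.channels),
        "accumulated": {"tp": r.accumulated.tp, "fp": r.accumulated.fp,
                        "fn": r.accumulated.fn, "tn": r.accumulated.tn},
        "micro": _metrics_dict(r.micro),
        "macro": _metrics_dict(r.macro),
        "per_fold": [
            {"subject_id": sid,
             "counts": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
             "metrics": _metrics_dict(m)}
            for sid, cm, m in r.per_fold
        ],
        "paired_mcnemar": {
            other: {"b": b, "c": c, "p": p} for other, (b, c, p) in r.paired.items()
        },
    }


def render_report_table(results: Mapping[str, EvaluationResult] | Sequence) -> str:
    """Human-readable accumulated-counts table (micro metrics).

    Columns mirror the conventional published layout: TPs, FPs, FNs, TNs,
    Rec, Prec, F1, Acc; counts use thousands separators.
    """
    if isinstance(results, Mapping):
        rows = list(results.values())
    else:
        rows = list(results)
    name_w = max(24, max((len(r.label) for r in rows), default=0) + 2)
    head = (f"{'configuration':<{name_w}}{'TPs':>8}{'FPs':>8}{'FNs':>8}{'TNs':>8}"
            f"{'Rec':>7}{'Prec':>7}{'F1':>7}{'Acc':>7}")
    lines = [head, "-" * len(head)]
    for r in rows:
        a, m = r.accumulated, r.micro
        lines.append(
            f"{r.label:<{name_w}}{a.tp:>8,}{a.fp:>8,}{a.fn:>8,}{a.tn:>8,}"
            f"{m.recall:>7.2f}{m.precision:>7.2f}{m.f1:>7.2f}{m.accuracy:>7.2f}"
        )
    return "\n".join(lines) + "\n"


def write_report(
    results: Mapping[str, EvaluationResult],
    path: str | Path,
    table_path: str | Path | None = None,
) -> None:
    """Structured JSON report plus a rendered table (atomic writes)."""
    path = Path(path)
    payload = {
        "format_version": FORMAT_VERSION,
        "results": {label: _result_dict(r) for label, r in results.items()},
    }
    _atomic_write_text(path, json.dumps(payload, indent=2) + "\n")
    table_path = Path(table_path) if table_path else path.with_suffix(".txt")
    _atomic_write_text(table_path, render_report_table(results))


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_predictions(
    dataset: FeaturizedDataset,
    results: Mapping[str, EvaluationResult],
    path: str | Path,
) -> None:
    """Per-window prediction dump (subject, start, truth, one column per config)."""
    labels = list(results)
    with open(Path(path), "w") as fh:
        fh.write("subject_id,start_s,truth," + ",".join(labels) + "\n")
        for i in range(len(dataset.labels)):
            preds = ",".join(str(int(results[l].predictions[i])) for l in labels)
            fh.write(
                f"{dataset.subject_ids[i]},{dataset.starts_s[i]!r},"
                f"{int(dataset.labels[i])},{preds}\n"
            )


def write_sfs_trace(trace, path: str | Path) -> None:
    """Delimited (step, channel, score) rows, ready for a selection curve plot."""
    with open(Path(path), "w") as fh:
        fh.write("step,channel,subset,score\n")
        for k, (ch, subset, score) in enumerate(trace.steps, start=1):
            fh.write(f"{k},{ch},{'+'.join(subset)},{score!r}\n")


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
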
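import json

import numpy as np
import pytest

from smokesense import dataio
from smokesense.evaluate import (
    ConfusionMatrix,
    EvaluationResult,
    featurize_cohort,
    metrics,
)
from smokesense.presets import COMPACT_SPECTRO
from smokesense.sfs import SfsTrace
from smokesense.synthio import ACTIVITIES, ActivityLog, generate_subject

from conftest import make_recording


@pytest.fixture()
def rec():
    return make_recording(12.0, seed=4)


class TestRecordingRoundTrip:
    def test_lossless_for_semg_and_precise_for_imu(self, rec, tmp_path):
        path = tmp_path / "rec.csv"
        dataio.write_recording(rec, path)
        back = dataio.read_recording(path)
        assert back.subject_id == rec.subject_id
        assert back.sample_rate_hz == rec.sample_rate_hz
        assert np.array_equal(back.semg, rec.semg)
        assert np.allclose(back.accel, rec.accel, atol=5e-7)
        assert np.allclose(back.gyro, rec.gyro, atol=5e-7)

    def test_generated_subject_roundtrip(self, mini_protocol, mini_params, tmp_path):
        rec, _ = generate_subject(mini_protocol, mini_params, "S09")
        path = tmp_path / "s09.csv"
        dataio.write_recording(rec, path)
        assert np.array_equal(dataio.read_recording(path).semg, rec.semg)


class TestRecordingErrors:
    def _write(self, tmp_path, body, n_emg=8):
        path = tmp_path / "bad.csv"
        header = (
            "# smokesense-recording v1\n# subject_id: X\n# sample_rate_hz: 200.0\n"
            f"# semg_resolution_bits: 8\n# n_semg_channels: {n_emg}\n"
        )
        path.write_text(header + body)
        return path

    def test_wrong_column_count(self, tmp_path):
        row = ",".join(["0.0"] + ["1"] * 7 + ["0.0"] * 6)  # 7 sEMG, 8 declared
        with pytest.raises(dataio.FormatError, match="columns"):
            dataio.read_recording(self._write(tmp_path, row + "\n"))

    def test_empty_file_is_an_error(self, tmp_path):
        with pytest.raises(dataio.FormatError, match="no data rows"):
            dataio.read_recording(self._write(tmp_path, ""))

    def test_out_of_range_semg_names_line(self, tmp_path):
        good = ",".join(["0.000"] + ["5"] * 8 + ["0.0"] * 6)
        bad = ",".join(["0.005"] + ["300"] + ["5"] * 7 + ["0.0"] * 6)
        with pytest.raises(dataio.FormatError, match="line 7"):
            dataio.read_recording(self._write(tmp_path, good + "\n" + bad + "\n"))

    def test_non_integer_semg_rejected(self, tmp_path):
        row = ",".join(["0.0"] + ["1.5"] + ["1"] * 7 + ["0.0"] * 6)
        with pytest.raises(dataio.FormatError, match="non-integer"):
            dataio.read_recording(self._write(tmp_path, row + "\n"))

    def test_missing_header_key(self, tmp_path):
        path = tmp_path / "nohdr.csv"
        path.write_text("0.0," + ",".join(["1"] * 14) + "\n")
        with pytest.raises(dataio.FormatError, match="header"):
            dataio.read_recording(path)


class TestActivityLog:
    def test_roundtrip_and_sorting(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text(
            "activity,start_s,end_s\n"
            "eating,100.0,160.0\n"
            "resting,0.0,60.0\n"  # out of order on purpose
            "smoking_sitting,60.0,100.0\n"
        )
        log = dataio.read_activity_log(path)
        assert [e[0] for e in log.events] == ["resting", "smoking_sitting", "eating"]

    def test_reversed_interval_rejected(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text("activity,start_s,end_s\nresting,10.0,5.0\n")
        with pytest.raises(dataio.FormatError, match="end"):
            dataio.read_activity_log(path)

    def test_overlap_rejected(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text(
            "activity,start_s,end_s\nresting,0,10\neating,5,15\n"
        )
        with pytest.raises(dataio.FormatError, match="overlap"):
            dataio.read_activity_log(path)

    def test_unknown_class_warns_and_passes_through(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text("activity,start_s,end_s\njuggling,0.0,10.0\n")
        with pytest.warns(UserWarning, match="juggling"):
            log = dataio.read_activity_log(path)
        assert log.events[0][0] == "juggling"
        assert log.smoking_intervals() == []

    def test_all_ten_protocol_activities_parse(self, tmp_path):
        path = tmp_path / "log.csv"
        rows = "".join(
            f"{a},{i * 10}.0,{i * 10 + 10}.0\n" for i, a in enumerate(ACTIVITIES)
        )
        path.write_text("activity,start_s,end_s\n" + rows)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no unknown-class warnings expected
            log = dataio.read_activity_log(path)
        assert len(log.events) == 10
        assert len(log.smoking_intervals()) == 4

    def test_writer_reader_roundtrip(self, tmp_path):
        log = ActivityLog(events=[("resting", 0.0, 30.5), ("smoking_sitting", 31.0, 90.25)])
        dataio.write_activity_log(log, tmp_path / "log.csv")
        assert dataio.read_activity_log(tmp_path / "log.csv").events == log.events


class TestManifest:
    def test_roundtrip(self, rec, tmp_path):
        dataio.write_recording(rec, tmp_path / "r.csv")
        dataio.write_activity_log(
            ActivityLog(events=[("resting", 0.0, 12.0)]), tmp_path / "l.csv"
        )
        m = dataio.DatasetManifest(
            [{"subject_id": "T01", "recording_path": "r.csv", "log_path": "l.csv"}]
        )
        dataio.write_manifest(m, tmp_path / "manifest.json")
        back = dataio.read_manifest(tmp_path / "manifest.json")
        assert len(back) == 1
        cohort = dataio.load_cohort(back, base=tmp_path)
        assert cohort[0][0].subject_id == "T01"

    def test_missing_file_rejected(self, tmp_path):
        m = dataio.DatasetManifest(
            [{"subject_id": "a", "recording_path": "nope.csv", "log_path": "nope2.csv"}]
        )
        dataio.write_manifest(m, tmp_path / "manifest.json")
        with pytest.raises(dataio.FormatError, match="missing file"):
            dataio.read_manifest(tmp_path / "manifest.json")

    def test_duplicate_subjects_rejected(self):
        with pytest.raises(dataio.FormatError, match="duplicate"):
            dataio.DatasetManifest(
                [{"subject_id": "a", "recording_path": "x", "log_path": "y"},
                 {"subject_id": "a", "recording_path": "z", "log_path": "w"}]
            )


def test_window_tensor_container_roundtrip(mini_cohort, tmp_path):
    ds = featurize_cohort(mini_cohort, ("emg1", "gyro_x"), scfg=COMPACT_SPECTRO)
    path = tmp_path / "tensors.h5"
    dataio.write_window_tensors(ds, path, config_echo={"note": "test"})
    back = dataio.read_window_tensors(path)
    assert np.array_equal(back.X, ds.X)
    assert np.array_equal(back.labels, ds.labels)
    assert list(back.subject_ids) == list(ds.subject_ids)
    assert back.channel_names == ds.channel_names
    sidecar = json.loads((tmp_path / "tensors.h5.json").read_text())
    assert sidecar["config"]["note"] == "test"


def _fake_result(label="IMU+sEMG (selected channels)"):
    cm = ConfusionMatrix(tp=5091, fp=697, fn=1135, tn=11574)
    m = metrics(cm)
    return EvaluationResult(
        label=label, channels=("emg1",), per_fold=[("S01", cm, m)],
        accumulated=cm, micro=m, macro=m,
        predictions=np.array([1, 0]), truth=np.array([1, 0]),
        paired={"IMU": (100, 10, 1.2e-8)},
    )


class TestReport:
    def test_single_configuration_single_row(self, tmp_path):
        res = {"IMU": _fake_result("IMU")}
        dataio.write_report(res, tmp_path / "report.json")
        table = (tmp_path / "report.txt").read_text().strip().splitlines()
        assert len(table) == 3  # header, rule, one data row

    def test_thousands_separators_in_rendered_counts(self):
        table = dataio.render_report_table({"x": _fake_result()})
        assert "11,574" in table and "5,091" in table

    def test_json_roundtrip_preserves_metrics(self, tmp_path):
        res = {"cfg": _fake_result("cfg")}
        dataio.write_report(res, tmp_path / "report.json")
        back = dataio.read_report(tmp_path / "report.json")
        row = back["results"]["cfg"]
        assert row["micro"]["precision"] == res["cfg"].micro.precision
        assert row["micro"]["f1"] == res["cfg"].micro.f1
        assert row["accumulated"]["tn"] == 11574
        assert row["paired_mcnemar"]["IMU"]["p"] == 1.2e-8

    def test_no_partial_report_left_behind(self, tmp_path):
        dataio.write_report({"a": _fake_result("a")}, tmp_path / "report.json")
        assert not list(tmp_path.glob("*.tmp"))


def test_sfs_trace_written_as_delimited_text(tmp_path):
    trace = SfsTrace(
        steps=[("emg6", ("emg6",), 0.81), ("emg1", ("emg6", "emg1"), 0.84)],
        criterion="f1",
    )
    dataio.write_sfs_trace(trace, tmp_path / "trace.csv")
    lines = (tmp_path / "trace.csv").read_text().strip().splitlines()
    assert lines[0] == "step,channel,subset,score"
    assert lines[1].startswith("1,emg6,emg6,")
    assert lines[2].startswith("2,emg1,emg6+emg1,")
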
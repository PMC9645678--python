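import numpy as np
import pytest

from smokesense.synthio import (
    ACTIVITIES,
    SMOKING_ACTIVITIES,
    ActivityLog,
    ActivityProtocol,
    GeneratorParams,
    generate_cohort,
    generate_subject,
    puff_train,
)


@pytest.fixture(scope="module")
def params():
    return GeneratorParams(seed=3)


class TestPuffTrain:
    def test_degenerate_session_yields_no_puffs(self, params):
        assert puff_train(100.0, 100.0, params, np.random.default_rng(0)) == []
        # shorter than one minimal puff
        assert puff_train(0.0, 1.0, params, np.random.default_rng(0)) == []

    def test_count_bounds_for_267s_session(self, params):
        # enumeration over extreme draws: all-minimal spacing gives the most
        # puffs, all-maximal the fewest
        d_lo, d_hi = params.puff_duration_s
        g_lo, g_hi = params.inter_puff_interval_s
        hi = 1
        while hi * (d_lo + g_lo) - g_lo + 0 <= 267 - d_lo:
            hi += 1
        lo = 0
        t = 0.0
        while t + d_hi <= 267:
            lo += 1
            t += d_hi + g_hi
        for seed in range(20):
            puffs = puff_train(0.0, 267.0, params, np.random.default_rng(seed))
            assert lo <= len(puffs) <= hi + 1
            assert 6 <= len(puffs) <= 13
            # non-overlapping, inside the session
            prev_end = 0.0
            for s, e in puffs:
                assert 0.0 <= s < e <= 267.0
                assert s >= prev_end
                assert d_lo <= e - s <= d_hi
                prev_end = e

    def test_seeded_determinism(self, params):
        a = puff_train(0.0, 300.0, params, np.random.default_rng(11))
        b = puff_train(0.0, 300.0, params, np.random.default_rng(11))
        assert a == b

    def test_reversed_session_rejected(self, params):
        with pytest.raises(ValueError):
            puff_train(10.0, 5.0, params, np.random.default_rng(0))


class TestProtocol:
    def test_nonsmoking_duration_cap(self):
        with pytest.raises(ValueError, match="exceeds"):
            ActivityProtocol(steps=[("reading", 301.0)], n_smoking_sessions=0)

    def test_eating_and_smoking_exempt_from_cap(self):
        ActivityProtocol(
            steps=[("eating", 600.0), ("smoking_sitting", 400.0)],
            n_smoking_sessions=1, smoking_session_duration_s=400.0,
        )

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            ActivityProtocol(steps=[])


class TestGenerateSubject:
    def test_log_matches_protocol(self, mini_protocol, params):
        rec, log = generate_subject(mini_protocol, params, "S01")
        smoking_events = [e for e in log.events if e[0] in SMOKING_ACTIVITIES]
        assert len(smoking_events) == mini_protocol.n_smoking_sessions
        assert len(log.events) == len(mini_protocol.steps)
        assert rec.n_samples == int(
            round(mini_protocol.total_duration_s * params.sample_rate_hz)
        )

    def test_semg_within_8bit_range(self, mini_protocol, params):
        rec, _ = generate_subject(mini_protocol, params, "S01")
        assert rec.semg.min() >= -128 and rec.semg.max() <= 127
        assert rec.semg.dtype.kind == "i"

    def test_gyro_rms_higher_inside_puffs(self, mini_protocol, params):
        rec, _ = generate_subject(mini_protocol, params, "S01")
        fs = rec.sample_rate_hz
        mag = np.linalg.norm(rec.gyro, axis=1)
        mask = np.zeros(rec.n_samples, dtype=bool)
        puffs = [g for g in rec.meta["gestures"] if g[2] in SMOKING_ACTIVITIES]
        assert puffs
        for g0, g1, _, _ in puffs:
            mask[int(g0 * fs) : int(g1 * fs)] = True
        rms_in = np.sqrt(np.mean(mag[mask] ** 2))
        rms_out = np.sqrt(np.mean(mag[~mask] ** 2))
        assert rms_in > rms_out

    def test_puff_semg_power_exceeds_resting_on_active_channels(
        self, mini_protocol, params
    ):
        rec, log = generate_subject(mini_protocol, params, "S01")
        fs = rec.sample_rate_hz
        puff_mask = np.zeros(rec.n_samples, dtype=bool)
        for g0, g1, act, _ in rec.meta["gestures"]:
            if act in SMOKING_ACTIVITIES:
                puff_mask[int(g0 * fs) : int(g1 * fs)] = True
        rest_mask = np.zeros(rec.n_samples, dtype=bool)
        for act, s, e in log.events:
            if act == "resting":
                rest_mask[int(s * fs) : int(e * fs)] = True
        active = rec.meta["effective_profiles"]["smoking_sitting"] > 0.05
        assert active.any()
        semg = rec.semg.astype(float)
        p_puff = (semg[puff_mask] ** 2).mean(axis=0)
        p_rest = (semg[rest_mask] ** 2).mean(axis=0)
        assert np.all(p_puff[active] > p_rest[active])

    def test_log_covers_recording_span(self, mini_protocol, params):
        rec, log = generate_subject(mini_protocol, params, "S01")
        covered = sum(e - s for _, s, e in log.events)
        n_gaps = len(log.events) - 1
        assert covered + n_gaps * mini_protocol.inter_activity_gap_s == pytest.approx(
            rec.duration_s
        )

    def test_seeded_determinism(self, mini_protocol, params):
        r1, _ = generate_subject(mini_protocol, params, "S01", np.random.default_rng(5))
        r2, _ = generate_subject(mini_protocol, params, "S01", np.random.default_rng(5))
        assert np.array_equal(r1.semg, r2.semg)
        assert np.array_equal(r1.accel, r2.accel)


class TestGenerateCohort:
    def test_sixteen_subjects_distinct_ids(self, mini_protocol, params):
        cohort = generate_cohort(16, mini_protocol, params)
        ids = [rec.subject_id for rec, _ in cohort]
        assert len(cohort) == 16
        assert len(set(ids)) == 16

    def test_same_master_seed_bitwise_identical(self, mini_protocol, params):
        a = generate_cohort(2, mini_protocol, params)
        b = generate_cohort(2, mini_protocol, params)
        for (ra, _), (rb, _) in zip(a, b):
            assert np.array_equal(ra.semg, rb.semg)
            assert np.array_equal(ra.gyro, rb.gyro)

    def test_subjects_differ(self, mini_protocol, params):
        cohort = generate_cohort(2, mini_protocol, params)
        assert not np.array_equal(cohort[0][0].semg, cohort[1][0].semg)

    def test_single_subject_rejected(self, mini_protocol, params):
        with pytest.raises(ValueError, match="LOSO"):
            generate_cohort(1, mini_protocol, params)


class TestParamValidation:
    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(semg_burst_gain=0.0)

    def test_activation_weights_bounded(self):
        profiles = GeneratorParams().channel_activation_profile
        profiles["smoking_sitting"] = np.full(8, 1.5)
        with pytest.raises(ValueError, match="in \\[0, 1\\]"):
            GeneratorParams(channel_activation_profile=profiles)

    def test_smoking_needs_a_positive_weight(self):
        profiles = GeneratorParams().channel_activation_profile
        profiles["smoking_sitting"] = np.zeros(8)
        with pytest.raises(ValueError, match="positive activation"):
            GeneratorParams(channel_activation_profile=profiles)

    def test_band_inside_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            GeneratorParams(semg_band_hz=(20.0, 120.0))


def test_activity_log_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        ActivityLog(events=[("resting", 0.0, 10.0), ("eating", 5.0, 15.0)])


def test_ten_activities_defined():
    assert len(ACTIVITIES) == 10
    assert sum(1 for a in ACTIVITIES if a in SMOKING_ACTIVITIES) == 4
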
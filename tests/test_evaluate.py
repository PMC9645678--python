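import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from smokesense.evaluate import (
    ConfusionMatrix,
    accumulate,
    confusion,
    loso_folds,
    mcnemar,
    metrics,
    run_experiment,
)
from smokesense.sfs import LogisticWindowSurrogate


class TestLosoFolds:
    def test_sixteen_subjects_sixteen_folds(self):
        ids = [f"S{i:02d}" for i in range(16)]
        folds = loso_folds(ids)
        assert len(folds) == 16
        assert {t for _, t in folds} == set(ids)
        for train, test in folds:
            assert test not in train
            assert len(train) == 15

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            loso_folds(["a", "a", "b"])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_folds(["a"])


class TestConfusion:
    def test_worked_examples(self):
        cm = confusion(np.array([1, 0, 1]), np.array([1, 0, 1]))
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 1, 0, 0)
        truth = np.array([1, 0, 1, 0])
        cm = confusion(1 - truth, truth)
        assert cm.tp == 0 and cm.tn == 0 and cm.fp == 2 and cm.fn == 2

    def test_against_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pred = rng.integers(0, 2, 200)
            truth = rng.integers(0, 2, 200)
            cm = confusion(pred, truth)
            tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
            for p, t in zip(pred, truth):
                key = ("t" if p == t else "f") + ("p" if p == 1 else "n")
                tally[key] += 1
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (
                tally["tp"], tally["fp"], tally["fn"], tally["tn"]
            )
            assert cm.total == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([1, 0]), np.array([1]))


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=7, fp=0, fn=0, tn=13))
        assert m.recall == m.precision == m.f1 == m.accuracy == 1.0
        assert not m.degenerate

    def test_degenerate_zero_denominators(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
        assert m.degenerate
        assert m.precision == m.recall == m.f1 == 0.0
        assert m.accuracy == 1.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_against_expansion_oracle(self):
        # rebuild the label-pair multiset from counts and recompute with sklearn
        from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 50, 4)
            cm = ConfusionMatrix(int(tp), int(fp), int(fn), int(tn))
            pred = np.r_[np.ones(tp), np.ones(fp), np.zeros(fn), np.zeros(tn)]
            truth = np.r_[np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)]
            m = metrics(cm)
            assert m.precision == pytest.approx(precision_score(truth, pred))
            assert m.recall == pytest.approx(recall_score(truth, pred))
            assert m.f1 == pytest.approx(f1_score(truth, pred))
            assert m.accuracy == pytest.approx(accuracy_score(truth, pred))


class TestAccumulate:
    def test_identity_and_sum(self):
        a = ConfusionMatrix(1, 2, 3, 4)
        b = ConfusionMatrix(10, 20, 30, 40)
        assert accumulate([a]) == a
        s = accumulate([a, b])
        assert (s.tp, s.fp, s.fn, s.tn) == (11, 22, 33, 44)

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        mats = [ConfusionMatrix(*map(int, rng.integers(0, 9, 4))) for _ in range(6)]
        perm = [mats[i] for i in rng.permutation(6)]
        assert accumulate(mats) == accumulate(perm)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accumulate([])


class TestMcnemar:
    def test_identical_predictions(self):
        t = np.array([1, 0, 1, 0])
        p = np.array([1, 1, 1, 0])
        assert mcnemar(p, p, t) == (0, 0, 1.0)

    def test_one_sided_discordance_closed_form(self):
        truth = np.zeros(20, dtype=int)
        pred_a = np.zeros(20, dtype=int)
        pred_b = np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)]
        b, c, p = mcnemar(pred_a, pred_b, truth)
        assert (b, c) == (10, 0)
        assert p == pytest.approx(2 * 0.5**10)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 2, 100)
        pa = rng.integers(0, 2, 100)
        pb = rng.integers(0, 2, 100)
        b1, c1, p1 = mcnemar(pa, pb, t)
        b2, c2, p2 = mcnemar(pb, pa, t)
        assert (b1, c1) == (c2, b2)
        assert p1 == pytest.approx(p2)

    def test_matches_statsmodels_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            t = rng.integers(0, 2, 80)
            pa = np.where(rng.random(80) < 0.8, t, 1 - t)
            pb = np.where(rng.random(80) < 0.7, t, 1 - t)
            b, c, p = mcnemar(pa, pb, t)
            table = [[0, b], [c, 0]]  # only discordant cells matter
            sm = sm_mcnemar(table, exact=True)
            assert p == pytest.approx(float(sm.pvalue))

    def test_chi2_close_to_exact_under_null(self):
        # discordant windows split by a fair coin (the null): the
        # continuity-corrected chi-square tracks the exact p within 10 %
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(50, 300))
            b = int(rng.binomial(n, 0.5))
            c = n - b
            truth = np.zeros(n, dtype=int)
            pa = np.r_[np.ones(b), np.zeros(c)].astype(int)
            pb = 1 - pa
            _, _, p_exact = mcnemar(pb, pa, truth)  # A wrong on b, B wrong on c
            _, _, p_chi2 = mcnemar(pb, pa, truth, method="chi2")
            assert 0 < p_exact <= 1
            assert p_chi2 == pytest.approx(p_exact, rel=0.10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(np.zeros(3), np.zeros(4), np.zeros(3))


@pytest.fixture(scope="module")
def results(mini_cohort, mini_dataset):
    configs = {
        "sEMG": ("emg1", "emg3", "emg6"),
        "IMU": ("accel_x", "gyro_x"),
        "fused": ("emg1", "emg3", "emg6", "accel_x", "gyro_x"),
    }
    return run_experiment(
        mini_cohort, configs, seed=0, dataset=mini_dataset,
        classifier_factory=lambda shape, s: LogisticWindowSurrogate(shape, s),
    )


class TestRunExperiment:

    def test_one_result_row_per_configuration(self, results, mini_dataset):
        assert set(results) == {"sEMG", "IMU", "fused"}
        for r in results.values():
            assert len(r.per_fold) == 3  # one fold per subject

    def test_count_conservation(self, results, mini_dataset):
        n = len(mini_dataset.labels)
        for r in results.values():
            assert r.accumulated.total == n
            for sid, cm, _ in r.per_fold:
                assert cm.total == int((mini_dataset.subject_ids == sid).sum())
            assert sum(cm.total for _, cm, _ in r.per_fold) == n

    def test_accumulated_equals_fold_sum(self, results):
        for r in results.values():
            s = accumulate([cm for _, cm, _ in r.per_fold])
            assert s == r.accumulated

    def test_paired_mcnemar_present_and_symmetric(self, results):
        b, c, p = results["sEMG"].paired["fused"]
        b2, c2, p2 = results["fused"].paired["sEMG"]
        assert (b, c) == (c2, b2) and p == p2
        assert 0 < p <= 1

    def test_loso_purity_no_test_leakage(self, mini_cohort, mini_dataset):
        """Standardization and training must never see the test subject."""
        from smokesense.spectra import fit_standardizer, apply_standardizer

        seen = []

        class Spy(LogisticWindowSurrogate):
            def fit(self, X, sequences, train_cfg=None):
                seen.append(("fit", X.copy(), np.asarray(sequences.labels).copy()))
                return super().fit(X, sequences, train_cfg)

            def predict(self, X, sequences, threshold=0.5):
                seen.append(("predict", X.copy(), None))
                return super().predict(X, sequences, threshold)

        subset = ("emg1", "accel_x")
        run_experiment(
            mini_cohort, {"cfg": subset}, seed=0, dataset=mini_dataset,
            classifier_factory=lambda shape, s: Spy(shape, s),
        )
        ch_idx = mini_dataset.channel_indices(subset)
        Xc = mini_dataset.X[..., ch_idx]
        subjects = list(dict.fromkeys(mini_dataset.subject_ids))
        fits = [s for s in seen if s[0] == "fit"]
        preds = [s for s in seen if s[0] == "predict"]
        assert len(fits) == len(preds) == len(subjects)
        for (_, Xtr, ytr), (_, Xte, _), test_id in zip(fits, preds, subjects):
            train_mask = mini_dataset.subject_ids != test_id
            # training set is exactly the non-test windows...
            assert Xtr.shape[0] == int(train_mask.sum())
            assert np.array_equal(ytr, mini_dataset.labels[train_mask])
            # ...standardized with statistics fitted on those windows alone
            stats = fit_standardizer(Xc[train_mask], subset)
            assert np.allclose(Xtr, apply_standardizer(Xc[train_mask], stats))
            assert np.allclose(Xte, apply_standardizer(Xc[~train_mask], stats))
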
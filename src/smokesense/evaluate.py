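"""Leave-one-subject-out evaluation, metrics, and paired comparison.

Each subject's entire recording is held out once; per-fold confusion matrices
are element-wise accumulated over folds.  Metrics are reported under two
conventions, labeled explicitly: *micro* (computed from the accumulated
counts) and *macro* (mean of per-fold metrics) — published summary tables in
this field often mix the two, so both are always available.

Featurization statistics (the per-channel spectrogram standardization) are
fitted on the training folds only, so no test-subject sample influences
training in any way.

McNemar's paired test compares two classifiers on the same windows via their
discordant counts: ``b`` windows where A is correct and B wrong, ``c`` the
converse.  The default is the exact two-sided binomial test of ``min(b, c)``
successes in ``b + c`` fair-coin trials, valid at any count; a
continuity-corrected chi-square variant is available for large ``b + c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .net import CnnLstm, ModelConfig, SequenceSet, TrainConfig, make_sequences
from .spectra import SpectrogramConfig, apply_standardizer, featurize_stack, fit_standardizer
from .synthio import ActivityLog, SensorRecording
from .windows import WindowingConfig, label_windows, segment

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "EvaluationResult",
    "FeaturizedDataset",
    "loso_folds",
    "confusion",
    "metrics",
    "accumulate",
    "mcnemar",
    "featurize_cohort",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class Metrics:
    recall: float
    precision: float
    f1: float
    accuracy: float
    degenerate: bool = False  # some denominator was zero; affected metrics are 0


def loso_folds(cohort: Sequence) -> list[tuple[list[str], str]]:
    """(train subjects, test subject) pairs, one fold per subject.

    ``cohort`` may be a list of subject ids or of (recording, log) pairs.
    """
    ids: list[str] = []
    for item in cohort:
        if isinstance(item, str):
            ids.append(item)
        else:
            rec = item[0] if isinstance(item, tuple) else item
            ids.append(rec.subject_id)
    if len(ids) < 2:
        raise ValueError("LOSO needs at least two subjects")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in cohort")
    return [([s for s in ids if s != test], test) for test in ids]


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Tally binary predictions against truth (positive class = 1)."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    tn = int(np.sum(~predicted & ~truth))
    return ConfusionMatrix(tp, fp, fn, tn)


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Recall, precision, F1 (harmonic mean) and accuracy from counts.

    Zero-denominator cases yield 0 for the affected metric and set the
    ``degenerate`` flag; an all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion matrix")
    degenerate = False
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision, degenerate = 0.0, True
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    accuracy = (cm.tp + cm.tn) / cm.total
    return Metrics(recall=recall, precision=precision, f1=f1, accuracy=accuracy,
                   degenerate=degenerate)


def accumulate(folds: Sequence[ConfusionMatrix]) -> ConfusionMatrix:
    """Element-wise sum of per-fold confusion matrices."""
    if not folds:
        raise ValueError("cannot accumulate an empty list of confusion matrices")
    out = folds[0]
    for cm in folds[1:]:
        out = out + cm
    return out


def mcnemar(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    truth: np.ndarray,
    method: str = "exact",
) -> tuple[int, int, float]:
    """Paired McNemar comparison of two classifiers on the same windows.

    Returns ``(b, c, p)`` with ``b`` = windows A got right and B wrong,
    ``c`` = the converse.  ``method='exact'`` uses the two-sided binomial
    test at rate 0.5; ``method='chi2'`` the continuity-corrected chi-square
    approximation.
    """
    pred_a = np.asarray(pred_a).astype(bool)
    pred_b = np.asarray(pred_b).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("pred_a, pred_b and truth must have equal lengths")
    correct_a = pred_a == truth
    correct_b = pred_b == truth
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    n = b + c
    if n == 0:
        return b, c, 1.0
    if method == "exact":
        p = float(sstats.binomtest(min(b, c), n, 0.5).pvalue)
    elif method == "chi2":
        stat = (abs(b - c) - 1) ** 2 / n
        p = float(sstats.chi2.sf(stat, df=1))
    else:
        raise ValueError(f"unknown McNemar method {method!r}")
    return b, c, min(p, 1.0)


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------


@dataclass
class FeaturizedDataset:
    """All windows of a cohort featurized over a common channel set.

    ``X`` is unstandardized (standardization is fitted per fold on training
    subjects only); windows are ordered by subject, then by start time.
    """

    X: np.ndarray  # (n_windows, F, T, C)
    labels: np.ndarray  # (n_windows,)
    subject_ids: np.ndarray  # (n_windows,) str
    starts_s: np.ndarray  # (n_windows,)
    channel_names: tuple[str, ...]

    def channel_indices(self, subset: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.channel_names.index(c) for c in subset])
        except ValueError as exc:
            raise KeyError(f"channel not in featurized set: {exc}") from exc


def featurize_cohort(
    cohort: Sequence[tuple[SensorRecording, ActivityLog]],
    channels: Sequence[str],
    wcfg: WindowingConfig | None = None,
    scfg: SpectrogramConfig | None = None,
) -> FeaturizedDataset:
    """Segment, label and featurize every recording over ``channels``."""
    wcfg = wcfg or WindowingConfig()
    scfg = scfg or SpectrogramConfig()
    stacks, labels, sids, starts = [], [], [], []
    for rec, log in cohort:
        ws = label_windows(segment(rec, wcfg), log)
        stacks.append(featurize_stack(ws, rec, channels, scfg))
        labels.append(ws.labels)
        sids.append(np.full(len(ws), rec.subject_id, dtype=object))
        starts.append(ws.starts_s)
    return FeaturizedDataset(
        X=np.concatenate(stacks, axis=0),
        labels=np.concatenate(labels).astype(np.int8),
        subject_ids=np.concatenate(sids),
        starts_s=np.concatenate(starts),
        channel_names=tuple(channels),
    )


@dataclass
class EvaluationResult:
    """Per-fold and accumulated LOSO results for one sensor configuration."""

    label: str
    channels: tuple[str, ...]
    per_fold: list[tuple[str, ConfusionMatrix, Metrics]]
    accumulated: ConfusionMatrix
    micro: Metrics
    macro: Metrics
    predictions: np.ndarray  # (n_windows,) 0/1 aligned with the dataset order
    truth: np.ndarray
    paired: dict[str, tuple[int, int, float]] = field(default_factory=dict)

    def summary(self) -> str:
        m = self.micro
        return (
            f"{self.label}: TP={self.accumulated.tp} FP={self.accumulated.fp} "
            f"FN={self.accumulated.fn} TN={self.accumulated.tn} | micro "
            f"Rec={m.recall:.3f} Prec={m.precision:.3f} F1={m.f1:.3f} Acc={m.accuracy:.3f}"
        )


def _default_classifier_factory(mcfg: ModelConfig | None):
    def make(input_shape: tuple[int, int, int], seed: int) -> CnnLstm:
        return CnnLstm(input_shape, mcfg, seed=seed)

    return make


def _fold_seed(master: int, config_i: int, fold_i: int) -> int:
    ss = np.random.SeedSequence([master, config_i, fold_i])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    cohort: Sequence[tuple[SensorRecording, ActivityLog]],
    configurations: Mapping[str, Sequence[str]],
    seed: int = 0,
    wcfg: WindowingConfig | None = None,
    scfg: SpectrogramConfig | None = None,
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
    classifier_factory: Callable | None = None,
    dataset: FeaturizedDataset | None = None,
) -> dict[str, EvaluationResult]:
    """LOSO train/evaluate each sensor configuration; pairwise McNemar.

    ``configurations`` maps a label (e.g. "IMU+sEMG") to its channel subset.
    A pre-featurized ``dataset`` covering the union of all channels may be
    passed to avoid recomputation.  Per-(configuration, fold) seeds derive
    deterministically from ``seed``.
    """
    if not configurations:
        raise ValueError("need at least one sensor configuration")
    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    factory = classifier_factory or _default_classifier_factory(mcfg)

    if dataset is None:
        union: list[str] = []
        for subset in configurations.values():
            for ch in subset:
                if ch not in union:
                    union.append(ch)
        dataset = featurize_cohort(cohort, union, wcfg, scfg)

    folds = loso_folds([sid for sid in dict.fromkeys(dataset.subject_ids)])
    results: dict[str, EvaluationResult] = {}
    for ci, (label, subset) in enumerate(configurations.items()):
        ch_idx = dataset.channel_indices(subset)
        Xc = dataset.X[..., ch_idx]
        per_fold = []
        pred_all = np.full(len(dataset.labels), -1, dtype=np.int8)
        for fi, (_train_ids, test_id) in enumerate(folds):
            test_mask = dataset.subject_ids == test_id
            train_mask = ~test_mask
            stats = fit_standardizer(Xc[train_mask], tuple(subset))
            Xtr = apply_standardizer(Xc[train_mask], stats)
            Xte = apply_standardizer(Xc[test_mask], stats)
            seq_tr = make_sequences(
                dataset.subject_ids[train_mask], dataset.labels[train_mask],
                mcfg.sequence_length,
            )
            seq_te = make_sequences(
                dataset.subject_ids[test_mask], dataset.labels[test_mask],
                mcfg.sequence_length,
            )
            fseed = _fold_seed(seed, ci, fi)
            clf = factory((Xtr.shape[1], Xtr.shape[2], Xtr.shape[3]), fseed)
            clf.fit(Xtr, seq_tr, tcfg)
            _, pred = clf.predict(Xte, seq_te)
            pred_all[test_mask] = pred
            cm = confusion(pred, dataset.labels[test_mask])
            per_fold.append((test_id, cm, metrics(cm)))
        acc = accumulate([cm for _, cm, _ in per_fold])
        macro = Metrics(
            recall=float(np.mean([m.recall for _, _, m in per_fold])),
            precision=float(np.mean([m.precision for _, _, m in per_fold])),
            f1=float(np.mean([m.f1 for _, _, m in per_fold])),
            accuracy=float(np.mean([m.accuracy for _, _, m in per_fold])),
            degenerate=any(m.degenerate for _, _, m in per_fold),
        )
        results[label] = EvaluationResult(
            label=label,
            channels=tuple(subset),
            per_fold=per_fold,
            accumulated=acc,
            micro=metrics(acc),
            macro=macro,
            predictions=pred_all,
            truth=dataset.labels.copy(),
        )

    labels = list(results)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            b, c, p = mcnemar(
                results[la].predictions, results[lb].predictions, dataset.labels
            )
            results[la].paired[lb] = (b, c, p)
            results[lb].paired[la] = (c, b, p)
    return results
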
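"""Sequential forward selection (SFS) of sEMG channels.

A greedy wrapper around the classifier: starting from an empty (or fixed
base) subset, each step tries every remaining candidate channel appended to
the current subset, trains and scores the classifier, and keeps the best
addition; ties break toward the lowest channel index.  The resulting trace
(one score per step) makes the classic channels-vs-score selection curve, and
``best_subset`` returns the prefix with the maximal score — a subset can beat
the full channel set when extra channels are redundant or noisy.

Scoring defaults to F1 under a cheap grouped subject-wise holdout (full LOSO
per candidate is quadratic in subjects x channels); full-LOSO scoring and an
accuracy criterion remain available.  The classifier is pluggable: the
CNN-LSTM at reduced epochs for real runs, or the lightweight logistic
surrogate below for fast selection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .evaluate import FeaturizedDataset, confusion, loso_folds, metrics
from .net import CnnLstm, ModelConfig, SequenceSet, TrainConfig, make_sequences
from .spectra import apply_standardizer, fit_standardizer

__all__ = [
    "ChannelSubset",
    "SfsTrace",
    "sfs_select",
    "best_subset",
    "LogisticWindowSurrogate",
]


@dataclass(frozen=True)
class ChannelSubset:
    """Ordered, duplicate-free list of channel identifiers."""

    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel subset contains duplicates")

    def __iter__(self):
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)


@dataclass
class SfsTrace:
    """One (added channel, subset so far, score) record per greedy step."""

    steps: list[tuple[str, tuple[str, ...], float]]
    criterion: str

    def __post_init__(self) -> None:
        prev: tuple[str, ...] = ()
        for ch, subset, score in self.steps:
            if not np.isfinite(score):
                raise ValueError("SFS scores must be finite")
            if subset[:-1] != prev or subset[-1] != ch:
                raise ValueError("SFS subsets must be nested, growing by one")
            prev = subset


class LogisticWindowSurrogate:
    """Cheap per-window stand-in classifier with the CnnLstm interface.

    Summarizes each window tensor by per-channel mean and standard deviation
    of the (log-magnitude) spectrogram and fits a logistic regression.
    Sequences are used only for label alignment; each final window is
    predicted from its own features.
    """

    def __init__(self, input_shape: tuple[int, int, int], seed: int = 0):
        self.input_shape = tuple(input_shape)
        self.seed = seed
        self._clf = LogisticRegression(max_iter=500, random_state=seed)

    @staticmethod
    def _features(X: np.ndarray) -> np.ndarray:
        return np.concatenate([X.mean(axis=(1, 2)), X.std(axis=(1, 2))], axis=1)

    def fit(self, X: np.ndarray, sequences: SequenceSet,
            train_cfg: TrainConfig | None = None) -> "LogisticWindowSurrogate":
        y = np.asarray(sequences.labels)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self._clf.fit(self._features(X[sequences.final_index]), y)
        return self

    def predict(self, X: np.ndarray, sequences: SequenceSet,
                threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        probs = self._clf.predict_proba(self._features(X[sequences.final_index]))[:, 1]
        return probs, (probs >= threshold).astype(np.int8)


def _holdout_splits(
    subject_ids: np.ndarray, eval_scheme: str, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_mask, test_mask) pairs for the requested evaluation scheme."""
    uniq = list(dict.fromkeys(subject_ids))
    if len(uniq) < 2:
        raise ValueError("channel selection needs >= 2 subjects")
    if eval_scheme == "loso":
        pairs = [(None, test) for _, test in loso_folds(uniq)]
        test_sets = [{t} for _, t in pairs]
    elif eval_scheme == "holdout":
        rng = np.random.default_rng(seed)
        held = rng.choice(uniq, size=max(1, len(uniq) // 3), replace=False)
        test_sets = [set(held)]
    else:
        raise ValueError(f"unknown eval_scheme {eval_scheme!r}")
    out = []
    for ts in test_sets:
        test_mask = np.isin(subject_ids, list(ts))
        out.append((~test_mask, test_mask))
    return out


def _score_subset(
    dataset: FeaturizedDataset,
    subset: tuple[str, ...],
    criterion: str,
    splits: list[tuple[np.ndarray, np.ndarray]],
    seed: int,
    factory: Callable,
    tcfg: TrainConfig,
    sequence_length: int,
) -> float:
    ch_idx = dataset.channel_indices(subset)
    Xc = dataset.X[..., ch_idx]
    scores = []
    for si, (train_mask, test_mask) in enumerate(splits):
        stats = fit_standardizer(Xc[train_mask], subset)
        Xtr = apply_standardizer(Xc[train_mask], stats)
        Xte = apply_standardizer(Xc[test_mask], stats)
        seq_tr = make_sequences(
            dataset.subject_ids[train_mask], dataset.labels[train_mask], sequence_length
        )
        seq_te = make_sequences(
            dataset.subject_ids[test_mask], dataset.labels[test_mask], sequence_length
        )
        fseed = int(np.random.SeedSequence([seed, si]).generate_state(1)[0] % (2**31))
        clf = factory((Xc.shape[1], Xc.shape[2], len(subset)), fseed)
        clf.fit(Xtr, seq_tr, tcfg)
        _, pred = clf.predict(Xte, seq_te)
        m = metrics(confusion(pred, dataset.labels[test_mask]))
        scores.append(getattr(m, criterion))
    return float(np.mean(scores))


def sfs_select(
    dataset: FeaturizedDataset,
    candidate_channels: Sequence[str],
    max_channels: int,
    criterion: str = "f1",
    eval_scheme: str = "holdout",
    seed: int = 0,
    base_channels: Sequence[str] = (),
    classifier_factory: Callable | None = None,
    tcfg: TrainConfig | None = None,
    mcfg: ModelConfig | None = None,
) -> SfsTrace:
    """Greedy forward selection over ``candidate_channels``.

    At step k every remaining candidate is appended to the current subset,
    the classifier is trained and scored under ``eval_scheme``, and the
    argmax of ``criterion`` is kept (ties -> first candidate in the given
    order, i.e. lowest channel index).  ``base_channels`` are always included
    but never counted among the selected ones.
    """
    if max_channels < 1:
        raise ValueError("max_channels must be >= 1")
    candidates = list(candidate_channels)
    if max_channels > len(candidates):
        raise ValueError("max_channels exceeds the number of candidates")
    if criterion not in ("f1", "accuracy", "precision", "recall"):
        raise ValueError(f"unknown criterion {criterion!r}")
    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig(n_epochs=2)
    factory = classifier_factory or (lambda shape, s: CnnLstm(shape, mcfg, seed=s))
    splits = _holdout_splits(dataset.subject_ids, eval_scheme, seed)

    chosen: list[str] = []
    steps: list[tuple[str, tuple[str, ...], float]] = []
    remaining = list(candidates)
    for _step in range(max_channels):
        best_ch, best_score = None, -np.inf
        for ch in remaining:
            trial = tuple(base_channels) + tuple(chosen) + (ch,)
            score = _score_subset(
                dataset, trial, criterion, splits, seed, factory, tcfg,
                mcfg.sequence_length,
            )
            if score > best_score:
                best_ch, best_score = ch, score
        chosen.append(best_ch)
        remaining.remove(best_ch)
        steps.append((best_ch, tuple(chosen), best_score))
    return SfsTrace(steps=steps, criterion=criterion)


def best_subset(trace: SfsTrace) -> ChannelSubset:
    """Prefix subset with the maximal score (earliest step on ties)."""
    if not trace.steps:
        raise ValueError("empty SFS trace")
    scores = [s for _, _, s in trace.steps]
    k = int(np.argmax(scores))  # argmax returns the first maximum
    return ChannelSubset(channels=trace.steps[k][1])
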
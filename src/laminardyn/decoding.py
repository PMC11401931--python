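"""Trial-normalized temporal decoding and temporal cross-decoding.

Condition labels are decoded from layer-specific voxel patterns with a
linear SVM (cost 1) at each trial timepoint; for cross-decoding, the
classifier trained at one timepoint is tested at all timepoints in turn.
Preprocessing follows the run-wise filter/z-score + 17-TR epoch +
adjacent-TR averaging + per-trial spatial z-scoring recipe; training folds
are balanced over the four trial-transition subtypes (current x previous
condition) so carry-over effects cannot drive the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn import config_context
from sklearn.svm import SVC

from .containers import VoxelTimeSeries
from .exceptions import FoldError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TrialTensor:
    """Trials × voxels × timepoints array with labels.

    ``labels`` is the condition per trial, ``prev_labels`` the previous
    trial's condition (None when unknown — such trials may be tested on but
    never trained on), ``times`` the nominal seconds of each timepoint.
    """

    data: np.ndarray
    labels: np.ndarray
    prev_labels: np.ndarray
    times: np.ndarray
    subject: str | None = None
    layer: str | None = None
    roi: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("data must be trials x voxels x timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("tensor contains non-finite values")
        self.labels = np.asarray(self.labels, dtype=object)
        self.prev_labels = np.asarray(self.prev_labels, dtype=object)
        if len(self.labels) != self.data.shape[0] or len(self.prev_labels) != len(self.labels):
            raise ValidationError("labels/prev_labels must match the trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def classes(self) -> list[str]:
        return sorted(set(self.labels))


@dataclass
class FoldSet:
    """Cross-validation folds with transition-balanced training sets."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    n_folds: int
    subtype_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    train_per_subtype: int = 0


@dataclass
class DecodingTimecourse:
    accuracy: np.ndarray
    times: np.ndarray
    chance: float = 0.5
    subject: str | None = None
    layer: str | None = None


@dataclass
class CrossDecodingMatrix:
    """Train-time × test-time accuracy matrix a_ij (diagonal = a_ii)."""

    a: np.ndarray
    times: np.ndarray
    chance: float = 0.5
    subject: str | None = None
    layer: str | None = None


def preprocess_run(run: VoxelTimeSeries, hp_cutoff_s: float = 128.0) -> VoxelTimeSeries:
    """High-pass filter (third-order Butterworth, zero-phase) each voxel,
    then z-score it over the run (mean 0, SD 1). Zero-variance voxels are
    dropped with a log entry."""
    n_scans = run.n_scans
    if n_scans <= 2 * (hp_cutoff_s / run.tr_s):
        raise ValidationError(
            f"run too short ({n_scans} scans) for a {hp_cutoff_s}s high-pass cutoff"
        )
    fs = 1.0 / run.tr_s
    sos = sps.butter(3, 1.0 / hp_cutoff_s, btype="highpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, run.data, axis=1)
    sd = filt.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance voxel(s)", int((~keep).sum()))
    z = (filt[keep] - filt[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return VoxelTimeSeries(data=z, tr_s=run.tr_s, run=run.run, voxel_ids=run.voxel_ids[keep])


def epoch_trials(
    run: VoxelTimeSeries, events: pd.DataFrame, n_trs: int = 17
) -> TrialTensor:
    """Cut one epoch per trial starting at the nearest rounded-down TR.

    Trial t spans scan indices ``floor(onset/TR) .. floor(onset/TR)+n_trs-1``;
    trials whose window extends past the run end are dropped with a log
    entry (the last-trial edge case). Timepoint times are nominal
    ``0, TR, ..., (n_trs-1)*TR`` seconds.
    """
    starts = np.floor(events["onset_s"].to_numpy() / run.tr_s).astype(int)
    keep = starts + n_trs <= run.n_scans
    if not keep.all():
        logger.info(
            "dropping %d trial(s) extending past run end (run %s)",
            int((~keep).sum()), run.run,
        )
    idx = np.flatnonzero(keep)
    data = np.stack([run.data[:, s : s + n_trs] for s in starts[idx]], axis=0) if idx.size else np.empty((0, run.n_voxels, n_trs))
    prev = events["prev_condition"].to_numpy(dtype=object)[idx]
    prev = np.array([None if (p is None or (isinstance(p, float) and np.isnan(p))) else p for p in prev], dtype=object)
    return TrialTensor(
        data=data,
        labels=events["condition"].to_numpy(dtype=object)[idx],
        prev_labels=prev,
        times=np.arange(n_trs) * run.tr_s,
    )


def concat_tensors(tensors: list[TrialTensor]) -> TrialTensor:
    """Stack trials from several runs (same voxels and timepoint grid)."""
    if not tensors:
        raise ValidationError("nothing to concatenate")
    first = tensors[0]
    for t in tensors[1:]:
        if t.data.shape[1:] != first.data.shape[1:] or not np.allclose(t.times, first.times):
            raise ValidationError("tensors disagree on voxels or timepoint grid")
    return TrialTensor(
        data=np.concatenate([t.data for t in tensors], axis=0),
        labels=np.concatenate([t.labels for t in tensors]),
        prev_labels=np.concatenate([t.prev_labels for t in tensors]),
        times=first.times,
        subject=first.subject,
        layer=first.layer,
        roi=first.roi,
    )


def pair_average(t: TrialTensor) -> TrialTensor:
    """Moving average of adjacent TRs: decoding timepoint k is the mean of
    TRs k−1 and k, labelled by the later TR's time (the first TR is
    consumed)."""
    if t.n_timepoints < 2:
        raise ValidationError("need >= 2 timepoints to pair-average")
    data = 0.5 * (t.data[:, :, :-1] + t.data[:, :, 1:])
    return replace(t, data=data, times=t.times[1:])


def trial_normalize(t: TrialTensor) -> TrialTensor:
    """Spatial z-score per trial-timepoint: subtract the across-voxel mean
    and divide by the across-voxel SD, so uniform activation shifts or
    gains cannot inform the classifier. A zero spatial SD leaves the
    trial-timepoint mean-centered only (logged)."""
    if t.data.shape[1] < 2:
        raise ValidationError("need >= 2 voxels for trial normalization")
    mean = t.data.mean(axis=1, keepdims=True)
    sd = t.data.std(axis=1, ddof=0, keepdims=True)
    flat = sd == 0
    if flat.any():
        logger.warning("%d trial-timepoint(s) with zero spatial SD: mean-centering only", int(flat.sum()))
    return replace(t, data=(t.data - mean) / np.where(flat, 1.0, sd))


def build_folds(
    labels: np.ndarray,
    prev_labels: np.ndarray,
    seed: int,
    max_tries: int = 1000,
) -> FoldSet:
    """Transition-balanced cross-validation folds.

    The four transition subtypes are (current, previous) condition pairs.
    ``n_folds = 4 x min subtype count``; each fold trains on an equal
    random draw from every subtype (one fewer than the scarcest subtype's
    count, at least 1) and tests on all held-out trials, including trials
    with unknown previous condition. Fold train sets are pairwise distinct.
    """
    labels = np.asarray(labels, dtype=object)
    prev_labels = np.asarray(prev_labels, dtype=object)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise FoldError(f"need exactly two classes, got {classes}")
    trainable = np.array([p is not None for p in prev_labels])
    subtypes = [(c, p) for c in classes for p in classes]
    members = {
        st: np.flatnonzero(trainable & (labels == st[0]) & (prev_labels == st[1]))
        for st in subtypes
    }
    for st, m in members.items():
        if m.size == 0:
            raise FoldError(f"empty transition subtype {st}")
    min_count = min(m.size for m in members.values())
    n_folds = 4 * min_count
    m_train = max(min_count - 1, 1)
    rng = np.random.default_rng(seed)
    all_idx = np.arange(len(labels))
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    seen: set[frozenset] = set()
    tries = 0
    while len(folds) < n_folds:
        tries += 1
        if tries > max_tries * n_folds:
            raise FoldError("could not realize pairwise-distinct folds in bounded retries")
        train = np.sort(
            np.concatenate([rng.choice(m, size=m_train, replace=False) for m in members.values()])
        )
        key = frozenset(train.tolist())
        if key in seen:
            continue
        seen.add(key)
        test = np.setdiff1d(all_idx, train)
        folds.append((train, test))
    return FoldSet(
        folds=folds,
        n_folds=n_folds,
        subtype_counts={st: int(m.size) for st, m in members.items()},
        train_per_subtype=m_train,
    )


def _feature_zscore(X: np.ndarray) -> np.ndarray:
    """Per-voxel z-score within the given set (ddof 0); constant features
    are left centered."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return (X - mu) / np.where(sd == 0, 1.0, sd)


def _decode(
    t: TrialTensor,
    folds: FoldSet,
    train_tps: np.ndarray,
    test_tps: np.ndarray,
    cost: float = 1.0,
    perm_rng: np.random.Generator | None = None,
    diagonal: bool = False,
) -> np.ndarray:
    """Fold-averaged accuracy for every (train_tp, test_tp) pair.

    Per fold, features are z-scored on the training set and — independently
    — within the test set; a linear SVM (cost ``cost``) is fit per training
    timepoint and its decision function evaluated on all test timepoints in
    one pass. A decision value of exactly 0 predicts the lexicographically
    lower class. If ``perm_rng`` is given, training labels are shuffled
    within each fold's training set (test labels stay intact): the
    label-permutation null of the same procedure. With ``diagonal=True``
    only the matched pairs (train_tps[k], test_tps[k]) are evaluated and a
    1-D array is returned.
    """
    classes = t.classes()
    if len(classes) != 2:
        raise ValidationError("binary decoding requires exactly two classes")
    y = (t.labels == classes[1]).astype(int)
    if diagonal and train_tps.size != test_tps.size:
        raise ValidationError("diagonal mode needs matched train/test timepoints")
    acc = np.zeros(train_tps.size) if diagonal else np.zeros((train_tps.size, test_tps.size))
    with config_context(assume_finite=True):
        for train, test in folds.folds:
            ytr = y[train]
            if perm_rng is not None:
                ytr = perm_rng.permutation(ytr)
            if len(set(ytr)) < 2:
                raise ValidationError("single-class training fold")
            yte = y[test]
            Xte = {int(tp): _feature_zscore(t.data[test, :, tp]) for tp in np.unique(test_tps)}
            for i, tp in enumerate(train_tps):
                Xtr = t.data[train, :, tp]
                mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
                Xtr = (Xtr - mu) / np.where(sd == 0, 1.0, sd)
                clf = SVC(kernel="linear", C=cost)
                clf.fit(Xtr, ytr)
                w, b = clf.coef_[0], clf.intercept_[0]
                if diagonal:
                    pred = (Xte[int(test_tps[i])] @ w + b > 0).astype(int)
                    acc[i] += float(np.mean(pred == yte))
                else:
                    for j, ttp in enumerate(test_tps):
                        pred = (Xte[int(ttp)] @ w + b > 0).astype(int)
                        acc[i, j] += float(np.mean(pred == yte))
    return acc / folds.n_folds


def decode_timepoint(
    t: TrialTensor, folds: FoldSet, train_tp: int, test_tp: int, cost: float = 1.0
) -> float:
    """Fold-averaged accuracy training at ``train_tp``, testing at ``test_tp``."""
    return float(
        _decode(t, folds, np.array([train_tp]), np.array([test_tp]), cost)[0, 0]
    )


def decode_timecourse(
    t: TrialTensor, folds: FoldSet, cost: float = 1.0
) -> DecodingTimecourse:
    """Accuracy per timepoint (train = test time)."""
    tps = np.arange(t.n_timepoints)
    acc = _decode(t, folds, tps, tps, cost, diagonal=True)
    return DecodingTimecourse(
        accuracy=acc, times=t.times, subject=t.subject, layer=t.layer
    )


def cross_decode(t: TrialTensor, folds: FoldSet, cost: float = 1.0) -> CrossDecodingMatrix:
    """Train-time × test-time accuracy matrix under the same folds.

    The diagonal equals :func:`decode_timecourse` under the same folds by
    construction (identical per-fold models and deterministic SVM); train
    and test trials never overlap at any matrix element.
    """
    tps = np.arange(t.n_timepoints)
    a = _decode(t, folds, tps, tps, cost)
    return CrossDecodingMatrix(a=a, times=t.times, subject=t.subject, layer=t.layer)
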
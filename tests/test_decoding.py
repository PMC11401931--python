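"""Decoding stack: preprocessing, epoching, folds, SVM, cross-decoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVC

from laminardyn.containers import VoxelTimeSeries
from laminardyn.decoding import (
    TrialTensor,
    _decode,
    build_folds,
    cross_decode,
    decode_timecourse,
    decode_timepoint,
    epoch_trials,
    pair_average,
    preprocess_run,
    trial_normalize,
)
from laminardyn.exceptions import FoldError, ValidationError


def _tensor(data, labels, prev=None, times=None):
    n = data.shape[0]
    return TrialTensor(
        data=data,
        labels=np.array(labels, dtype=object),
        prev_labels=np.array(prev if prev is not None else labels, dtype=object),
        times=times if times is not None else np.arange(data.shape[2]) * 2.0,
    )


class TestPreprocess:
    def test_zero_mean_unit_sd_per_voxel(self):
        rng = np.random.default_rng(0)
        run = VoxelTimeSeries(data=rng.normal(2.0, 3.0, size=(5, 300)), tr_s=2.0)
        out = preprocess_run(run)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10
        assert np.allclose(out.data.std(axis=1), 1.0, atol=1e-10)

    def test_slow_drift_suppressed(self):
        t = np.arange(300) * 2.0
        drift = np.sin(2 * np.pi * t / 600.0)  # period 600 s >> 128 s cutoff
        fast = np.sin(2 * np.pi * t / 20.0)
        run = VoxelTimeSeries(data=np.vstack([drift + 0.1 * fast]), tr_s=2.0)
        from scipy import signal as sps

        sos = sps.butter(3, 1 / 128.0, btype="highpass", fs=0.5, output="sos")
        filt = sps.sosfiltfilt(sos, run.data[0])
        assert np.sum(filt**2) < 0.05 * np.sum(run.data[0] ** 2)

    def test_white_noise_variance_preserved(self):
        rng = np.random.default_rng(1)
        run = VoxelTimeSeries(data=rng.normal(size=(3, 400)), tr_s=2.0)
        out = preprocess_run(run)
        assert np.allclose(out.data.std(axis=1), 1.0, atol=1e-10)

    def test_short_run_rejected(self):
        run = VoxelTimeSeries(data=np.random.default_rng(0).normal(size=(2, 100)), tr_s=2.0)
        with pytest.raises(ValidationError):
            preprocess_run(run, hp_cutoff_s=128.0)


class TestEpoch:
    def _run(self, n_scans=260):
        rng = np.random.default_rng(0)
        return VoxelTimeSeries(data=rng.normal(size=(3, n_scans)), tr_s=2.0)

    def _events(self, onsets):
        return pd.DataFrame(
            {
                "onset_s": onsets,
                "duration_s": 30.7,
                "condition": ["high", "low"] * (len(onsets) // 2)
                + ["high"] * (len(onsets) % 2),
                "run": 0,
                "run_type": "load",
                "trial_index": np.arange(len(onsets)),
                "prev_condition": [None] + ["high"] * (len(onsets) - 1),
            }
        )

    @pytest.mark.parametrize("onset,start", [(5.3, 2), (30.7, 15), (12.8, 6)])
    def test_floor_tr_start(self, onset, start):
        t = epoch_trials(self._run(), self._events([onset]))
        assert np.allclose(t.data[0], self._run().data[:, start : start + 17])

    def test_17_trs_per_epoch(self):
        t = epoch_trials(self._run(), self._events([5.3, 40.0]))
        assert t.data.shape == (2, 3, 17)
        assert np.allclose(t.times, np.arange(17) * 2.0)

    def test_overrunning_trial_dropped(self, caplog):
        # onset 490 -> start scan 245, 245+17 > 260
        t = epoch_trials(self._run(), self._events([5.3, 490.0]))
        assert t.n_trials == 1


class TestPairAverage:
    def test_constant_series_unchanged(self):
        t = _tensor(np.full((2, 3, 5), 4.0), ["a", "b"])
        out = pair_average(t)
        assert np.all(out.data == 4.0)
        assert out.data.shape[2] == 4

    def test_adjacent_means(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [0.0, 2.0, 4.0]
        out = pair_average(_tensor(data, ["a"]))
        assert out.data[0, 0].tolist() == [1.0, 3.0]
        assert out.times.tolist() == [2.0, 4.0]  # labelled by the later TR

    def test_white_noise_variance_halves(self):
        rng = np.random.default_rng(0)
        t = _tensor(rng.normal(size=(1000, 1, 2)), ["a"] * 1000)
        out = pair_average(t)
        assert out.data.var() == pytest.approx(0.5, rel=0.1)


class TestTrialNormalize:
    def test_three_voxel_zscore(self):
        data = np.array([[[1.0], [2.0], [3.0]]])
        out = trial_normalize(_tensor(data, ["a"]))
        assert np.allclose(out.data[0, :, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_uniform_offset_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 6, 3))
        a = trial_normalize(_tensor(data, ["a"] * 4))
        b = trial_normalize(_tensor(data + 100.0, ["a"] * 4))
        assert np.allclose(a.data, b.data, atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(-50, 50), st.floats(0.1, 10))
    def test_affine_invariance_property(self, offset, gain):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(2, 5, 2))
        a = trial_normalize(_tensor(data, ["a", "b"]))
        b = trial_normalize(_tensor(gain * data + offset, ["a", "b"]))
        assert np.allclose(a.data, b.data, atol=1e-8)

    def test_flat_pattern_mean_centered_only(self, caplog):
        data = np.full((1, 4, 1), 3.0)
        out = trial_normalize(_tensor(data, ["a"]))
        assert np.allclose(out.data, 0.0)


def _labels_with_counts(counts):
    """labels/prev_labels realizing given (cond, prev) subtype counts."""
    labels, prev = [], []
    for (c, p), n in counts.items():
        labels += [c] * n
        prev += [p] * n
    return np.array(labels, dtype=object), np.array(prev, dtype=object)


class TestFolds:
    def test_fold_count_formula(self):
        labels, prev = _labels_with_counts(
            {("a", "a"): 6, ("a", "b"): 8, ("b", "a"): 8, ("b", "b"): 8}
        )
        fs = build_folds(labels, prev, seed=0)
        assert fs.n_folds == 24

    def test_equal_subtype_counts_in_every_training_set(self):
        labels, prev = _labels_with_counts(
            {("a", "a"): 4, ("a", "b"): 4, ("b", "a"): 4, ("b", "b"): 4}
        )
        fs = build_folds(labels, prev, seed=1)
        assert fs.n_folds == 16
        for train, _ in fs.folds:
            sub = list(zip(labels[train], prev[train]))
            counts = {k: sub.count(k) for k in set(sub)}
            assert len(set(counts.values())) == 1
            assert len(counts) == 4

    @pytest.mark.parametrize("seed", range(100))
    def test_train_test_disjoint_and_folds_distinct(self, seed):
        labels, prev = _labels_with_counts(
            {("a", "a"): 5, ("a", "b"): 7, ("b", "a"): 7, ("b", "b"): 6}
        )
        fs = build_folds(labels, prev, seed=seed)
        seen = set()
        for train, test in fs.folds:
            assert len(np.intersect1d(train, test)) == 0
            key = frozenset(train.tolist())
            assert key not in seen
            seen.add(key)

    def test_unknown_prev_trials_test_only(self):
        labels, prev = _labels_with_counts(
            {("a", "a"): 4, ("a", "b"): 4, ("b", "a"): 4, ("b", "b"): 4}
        )
        labels = np.append(labels, ["a"])
        prev = np.append(prev, [None])
        fs = build_folds(labels, prev, seed=0)
        first_trial = len(labels) - 1
        for train, test in fs.folds:
            assert first_trial not in train
            assert first_trial in test

    def test_empty_subtype_errors(self):
        labels, prev = _labels_with_counts(
            {("a", "a"): 4, ("a", "b"): 4, ("b", "a"): 4}
        )
        with pytest.raises(FoldError, match="b.*b"):
            build_folds(labels, prev, seed=0)

    def test_seed_determinism(self):
        labels, prev = _labels_with_counts(
            {("a", "a"): 5, ("a", "b"): 5, ("b", "a"): 5, ("b", "b"): 5}
        )
        a = build_folds(labels, prev, seed=9)
        b = build_folds(labels, prev, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a.folds, b.folds):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)


def _max_margin_oracle(Xtr, ytr):
    """Exact hard-margin maximum-margin separator in 2-D by enumerating
    support-vector configurations (pairs and class-pair triples)."""
    A = Xtr[ytr == 0]
    B = Xtr[ytr == 1]

    def feasible(w, b, margin):
        fa = np.max(A @ w + b)
        fb = np.min(B @ w + b)
        return fa <= -margin + 1e-9 and fb >= margin - 1e-9

    best = (None, None, -1.0)
    # pair candidates: boundary is the perpendicular bisector
    for a in A:
        for b_pt in B:
            d = b_pt - a
            nrm = np.linalg.norm(d)
            if nrm == 0:
                continue
            w = d / nrm
            bias = -w @ (a + b_pt) / 2.0
            m = nrm / 2.0
            if feasible(w, bias, m) and m > best[2]:
                best = (w, bias, m)
    # triple candidates: boundary parallel to an edge within one class
    for P, Q, sgn in ((A, B, 1.0), (B, A, -1.0)):
        for i in range(len(P)):
            for j in range(i + 1, len(P)):
                e = P[j] - P[i]
                if np.linalg.norm(e) == 0:
                    continue
                for q in Q:
                    d = q - P[i]
                    w = d - (d @ e) / (e @ e) * e
                    nrm = np.linalg.norm(w)
                    if nrm == 0:
                        continue
                    w = sgn * w / nrm
                    m = abs((q - P[i]) @ w) / 2.0
                    bias = -w @ (P[i] + q) / 2.0
                    if feasible(w, bias, m) and m > best[2]:
                        best = (w, bias, m)
    return best


class TestSVM:
    def test_separable_toy_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        n = 16
        data = np.zeros((n, 2, 1))
        labels = ["a"] * (n // 2) + ["b"] * (n // 2)
        data[: n // 2, 0, 0] = -1.0 + 0.05 * rng.normal(size=n // 2)
        data[n // 2 :, 0, 0] = 1.0 + 0.05 * rng.normal(size=n // 2)
        data[:, 1, 0] = 0.05 * rng.normal(size=n)
        prev = (["a", "b"] * n)[:n]
        t = _tensor(data, labels, prev)
        fs = build_folds(t.labels, t.prev_labels, seed=0)
        assert decode_timepoint(t, fs, 0, 0) == 1.0

    def test_matches_brute_force_max_margin(self):
        """The fitted linear SVM (c = 1) equals the exact maximum-margin
        separator on a well-separated 8-trial, 2-voxel worked example."""
        rng = np.random.default_rng(3)
        Xa = np.array([[-2.0, 0.5], [-2.5, -0.6], [-1.8, 1.2], [-2.2, 0.1]])
        Xb = np.array([[2.1, -0.3], [1.9, 0.8], [2.6, -0.9], [2.3, 0.4]])
        Xtr = np.vstack([Xa, Xb])
        ytr = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        clf = SVC(kernel="linear", C=1.0, tol=1e-8)
        clf.fit(Xtr, ytr)
        w_svm = clf.coef_[0] / np.linalg.norm(clf.coef_[0])
        b_svm = clf.intercept_[0] / np.linalg.norm(clf.coef_[0])
        w_o, b_o, margin = _max_margin_oracle(Xtr, ytr)
        assert margin > 1.0  # wide margin: soft and hard margin coincide
        assert np.allclose(w_svm, w_o, atol=1e-4)
        assert b_svm == pytest.approx(b_o, abs=1e-4)
        # identical predictions on a probe grid
        probes = rng.uniform(-3, 3, size=(50, 2))
        assert np.array_equal(
            clf.predict(probes), (probes @ w_o + b_o > 0).astype(int)
        )

    def test_shuffled_labels_decode_at_chance(self):
        """Label-shuffled data (200 trials) stays within the binomial 99% CI
        of 0.5 at each probed timepoint."""
        rng = np.random.default_rng(5)
        n = 200
        data = rng.normal(size=(n, 12, 4))
        labels = np.array((["a", "b"] * (n // 2)), dtype=object)
        rng.shuffle(labels)
        prev = np.roll(labels, 1)
        t = trial_normalize(_tensor(data, labels, prev))
        fs = build_folds(t.labels, t.prev_labels, seed=0)
        for tp in range(4):
            acc = decode_timepoint(t, fs, tp, tp)
            assert abs(acc - 0.5) < 2.576 * np.sqrt(0.25 / n) + 0.05

    def test_uniform_activation_difference_decodes_at_chance(self):
        """Classes differing only in overall activation (gain + offset on a
        spatially uniform component) are at chance after trial
        normalization."""
        rng = np.random.default_rng(8)
        n, v = 64, 10
        labels = np.array((["a", "a", "b", "b"] * (n // 4)), dtype=object)
        gain = np.where(labels == "a", 1.0, 2.5)
        data = (
            gain[:, None, None] * np.ones((n, v, 3))
            + np.where(labels == "a", 0.0, 0.8)[:, None, None]
            + 0.5 * rng.normal(size=(n, v, 3))
        )
        t = trial_normalize(_tensor(data, labels, np.roll(labels, 1)))
        fs = build_folds(t.labels, t.prev_labels, seed=1)
        accs = [decode_timepoint(t, fs, tp, tp) for tp in range(3)]
        assert abs(np.mean(accs) - 0.5) < 0.1


class TestCrossDecode:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(11)
        n, v, T = 40, 8, 5
        labels = np.array((["a", "a", "b", "b"] * (n // 4)), dtype=object)
        pat = rng.normal(size=(2, v))
        data = rng.normal(size=(n, v, T))
        for i, lab in enumerate(labels):
            data[i] += 1.5 * pat[int(lab == "b")][:, None]
        t = trial_normalize(_tensor(data, labels, np.roll(labels, 1)))
        return t, build_folds(labels, np.roll(labels, 1), seed=2)

    def test_diagonal_equals_timecourse(self, toy):
        t, fs = toy
        tc = decode_timecourse(t, fs)
        m = cross_decode(t, fs)
        assert np.allclose(np.diag(m.a), tc.accuracy)

    def test_stable_pattern_generalizes_off_diagonal(self, toy):
        t, fs = toy
        m = cross_decode(t, fs)
        off = m.a[~np.eye(m.a.shape[0], dtype=bool)]
        assert np.mean(np.abs(off - np.diag(m.a).mean())) < 0.05

    def test_identity_permutation_reproduces_empirical(self, toy):
        t, fs = toy

        class IdentityRng:
            def permutation(self, x):
                return x

        tps = np.arange(t.n_timepoints)
        emp = _decode(t, fs, tps, tps, diagonal=True)
        perm = _decode(t, fs, tps, tps, perm_rng=IdentityRng(), diagonal=True)
        assert np.array_equal(emp, perm)

    def test_seed_determinism(self, toy):
        t, _ = toy
        a = build_folds(t.labels, t.prev_labels, seed=3)
        b = build_folds(t.labels, t.prev_labels, seed=3)
        assert np.allclose(
            cross_decode(t, a).a, cross_decode(t, b).a
        )
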
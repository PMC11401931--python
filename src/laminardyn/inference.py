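"""Permutation-based group inference for decoding results.

Subject-level nulls rerun the decoding with training labels shuffled
(within fold training sets); population-level nulls draw one sample per
subject and convert the draw into a t statistic, many times. Significance
of timecourses and cross-decoding matrices uses cluster-permutation tests
(summed t of contiguous suprathreshold elements against the max-cluster
null); dynamic coding is a conjunction of two "off-diagonal lower than
diagonal" cluster tests; and the period × layer interaction uses a
permutation repeated-measures ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .decoding import FoldSet, TrialTensor, _decode
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: large finite stand-in for a zero-variance t statistic
_T_CAP = 1e12

#: 4-connectivity (edges, not corners) for 2-D clusters
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class NullDistribution:
    """Permutation samples of a statistic (accuracy or t) per element."""

    samples: np.ndarray  # n_samples x element shape
    level: str  # "subject" | "population"

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class Cluster:
    elements: list[tuple]  # time indices or (i, j) pairs
    summed_t: float
    p: float
    mean_d: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    tail: str
    t_obs: np.ndarray
    alpha: float = 0.05

    def significant_mask(self, alpha: float | None = None) -> np.ndarray:
        """Boolean map of elements inside clusters with p < alpha."""
        alpha = self.alpha if alpha is None else alpha
        mask = np.zeros(self.t_obs.shape, dtype=bool)
        for c in self.clusters:
            if c.p < alpha:
                for el in c.elements:
                    mask[el] = True
        return mask


@dataclass
class DynamicMask:
    """Off-diagonal elements with reliably lower accuracy than both of
    their diagonal partners, restricted to above-chance diagonals."""

    mask: np.ndarray
    test_vs_train_diag: ClusterResult
    test_vs_test_diag: ClusterResult


@dataclass
class AnovaResult:
    F: float
    eta_sq: float
    p: float
    df: tuple[int, int]
    design: str = "periods x layers, within-subject"


def _t_stat(x: np.ndarray, popmean: float, axis: int) -> np.ndarray:
    """One-sample t with zero-variance guards (0 when the mean equals the
    reference, ±cap otherwise)."""
    n = x.shape[axis]
    mean = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - popmean) / (sd / np.sqrt(n))
    degen = sd == 0
    if np.any(degen):
        t = np.where(degen & (mean == popmean), 0.0, t)
        t = np.where(degen & (mean != popmean), np.sign(mean - popmean) * _T_CAP, t)
    return t


def subject_null(
    t: TrialTensor,
    folds: FoldSet,
    n_perm: int = 250,
    seed: int = 0,
    mode: str = "diag",
    cost: float = 1.0,
) -> NullDistribution:
    """Label-permutation null of the decoding accuracy.

    Each permutation shuffles the training labels within every fold's
    training set (test labels stay intact for scoring) and reruns the exact
    classification procedure. ``mode="diag"`` yields per-timepoint
    accuracies (n_perm × T); ``mode="matrix"`` full cross-decoding matrices
    (n_perm × T × T).
    """
    rng = np.random.default_rng(seed)
    tps = np.arange(t.n_timepoints)
    samples = []
    for _ in range(n_perm):
        if mode == "diag":
            samples.append(_decode(t, folds, tps, tps, cost, perm_rng=rng, diagonal=True))
        elif mode == "matrix":
            samples.append(_decode(t, folds, tps, tps, cost, perm_rng=rng))
        else:
            raise ValidationError("mode must be 'diag' or 'matrix'")
    return NullDistribution(samples=np.stack(samples, axis=0), level="subject")


def population_null(
    subject_nulls: list[NullDistribution | np.ndarray],
    chance: float = 0.5,
    n_draws: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Population null of the group t statistic vs chance.

    Per draw, one sample is taken from every subject's null distribution
    and a one-sample t across subjects is computed per element; repeated
    ``n_draws`` times.
    """
    if len(subject_nulls) < 2:
        raise ValidationError("need >= 2 subjects")
    S = np.stack(
        [n.samples if isinstance(n, NullDistribution) else np.asarray(n) for n in subject_nulls],
        axis=0,
    )  # subjects x n_samples x elements...
    n_subj, n_samp = S.shape[0], S.shape[1]
    rng = np.random.default_rng(seed)
    idx = rng.integers(n_samp, size=(n_draws, n_subj))
    draws = S[np.arange(n_subj)[None, :], idx]  # n_draws x subjects x elements
    return NullDistribution(samples=_t_stat(draws, chance, axis=1), level="population")


def population_null_paired(
    subject_nulls_a: list[NullDistribution | np.ndarray],
    subject_nulls_b: list[NullDistribution | np.ndarray],
    n_draws: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Population null of the paired t between two layers' sampled values."""
    A = np.stack(
        [n.samples if isinstance(n, NullDistribution) else np.asarray(n) for n in subject_nulls_a],
        axis=0,
    )
    B = np.stack(
        [n.samples if isinstance(n, NullDistribution) else np.asarray(n) for n in subject_nulls_b],
        axis=0,
    )
    if A.shape != B.shape:
        raise ValidationError("layer null distributions disagree in shape")
    rng = np.random.default_rng(seed)
    n_subj, n_samp = A.shape[0], A.shape[1]
    idx_a = rng.integers(n_samp, size=(n_draws, n_subj))
    idx_b = rng.integers(n_samp, size=(n_draws, n_subj))
    subj = np.arange(n_subj)[None, :]
    diff = A[subj, idx_a] - B[subj, idx_b]
    return NullDistribution(samples=_t_stat(diff, 0.0, axis=1), level="population")


def _runs_1d(mask: np.ndarray) -> list[np.ndarray]:
    """Indices of maximal contiguous True runs."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append(np.arange(i, j + 1))
            i = j + 1
        else:
            i += 1
    return out


def _clusters_1d(t: np.ndarray, lo: np.ndarray | None, hi: np.ndarray | None) -> list[tuple[np.ndarray, float]]:
    """Same-sign contiguous suprathreshold clusters and their summed t.

    ``hi``/``lo`` are per-element thresholds (either may be None for a
    one-tailed test); two-sided clusters never mix signs.
    """
    clusters = []
    if hi is not None:
        for run in _runs_1d(t > hi):
            clusters.append((run, float(t[run].sum())))
    if lo is not None:
        for run in _runs_1d(t < lo):
            clusters.append((run, float(t[run].sum())))
    return clusters


def temporal_cluster_test(
    group_values: np.ndarray,
    pop_null: NullDistribution,
    tail: str = "one",
    alpha: float = 0.05,
    chance: float = 0.5,
) -> ClusterResult:
    """1-D cluster-permutation test of group accuracies (or differences).

    Pointwise t vs ``chance`` is thresholded at the pointwise permutation
    p < ``alpha`` under ``pop_null`` (same tail); maximal contiguous runs
    form clusters whose summed t is compared against the max-cluster summed
    t of each null draw. ``tail="one"`` tests above chance; ``"two"``
    allows both directions (same-sign clusters, |summed t| compared).
    """
    group_values = np.asarray(group_values, dtype=float)
    if group_values.ndim != 2 or group_values.shape[1] < 2:
        raise ValidationError("group_values must be subjects x timepoints (>= 2 timepoints)")
    n_subj = group_values.shape[0]
    t_obs = _t_stat(group_values, chance, axis=0)
    null = pop_null.samples  # n_draws x T
    if null.shape[1] != t_obs.size:
        raise ValidationError("null distribution does not match the timepoint grid")
    if tail == "one":
        hi = np.quantile(null, 1.0 - alpha, axis=0)
        lo = None
    elif tail == "two":
        hi = np.quantile(null, 1.0 - alpha / 2.0, axis=0)
        lo = np.quantile(null, alpha / 2.0, axis=0)
    else:
        raise ValidationError("tail must be 'one' or 'two'")

    def max_stat(tvec: np.ndarray) -> float:
        cl = _clusters_1d(tvec, lo, hi)
        return max((abs(s) for _, s in cl), default=0.0)

    null_max = np.array([max_stat(null[d]) for d in range(null.shape[0])])
    clusters = []
    for run, summed in _clusters_1d(t_obs, lo, hi):
        p = (1.0 + float(np.sum(null_max >= abs(summed)))) / (1.0 + null.shape[0])
        mean_d = float(np.mean(t_obs[run]) / np.sqrt(n_subj))
        clusters.append(
            Cluster(elements=[(int(i),) for i in run], summed_t=summed, p=p, mean_d=mean_d)
        )
    return ClusterResult(clusters=clusters, tail=tail, t_obs=t_obs, alpha=alpha)


def _matrix_clusters(
    t_map: np.ndarray,
    lo: np.ndarray | None,
    hi: np.ndarray | None,
    valid: np.ndarray,
) -> list[tuple[np.ndarray, float]]:
    """4-connected suprathreshold clusters of a 2-D t map."""
    out = []
    for thr, sign in ((hi, 1), (lo, -1)):
        if thr is None:
            continue
        supra = (t_map > thr) if sign == 1 else (t_map < thr)
        supra &= valid
        lab, n = ndimage.label(supra, structure=_STRUCT_4)
        for k in range(1, n + 1):
            idx = lab == k
            out.append((idx, float(t_map[idx].sum())))
    return out


def matrix_cluster_test(
    group_mats: np.ndarray,
    chance: float = 0.5,
    n_perm: int = 10_000,
    tail: str = "one",
    alternative: str = "greater",
    alpha: float = 0.05,
    seed: int = 0,
    exclude_diagonal: bool = False,
) -> ClusterResult:
    """2-D sign-permutation cluster test of cross-decoding matrices.

    Element-wise t vs ``chance`` across subjects; the null flips each
    subject's centered matrix by ±1 with probability ½. Elements with
    pointwise permutation p < ``alpha`` form 4-connected clusters; a
    cluster's summed t is compared to the null's maximum cluster summed t.
    """
    X = np.asarray(group_mats, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValidationError("group_mats must be subjects x train x test with >= 2 subjects")
    n_subj, T, _ = X.shape
    Xc = (X - chance).reshape(n_subj, -1)
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    ssq = np.sum(Xc**2, axis=0)  # invariant under sign flips
    means = flips @ Xc / n_subj  # n_perm x T*T
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ssq[None, :] - n_subj * means**2) / (n_subj - 1)
        var = np.clip(var, 0.0, None)
        t_null = means / np.sqrt(var / n_subj)
    t_null = np.nan_to_num(t_null, nan=0.0, posinf=_T_CAP, neginf=-_T_CAP)
    t_obs = _t_stat(X, chance, axis=0)

    valid = np.ones((T, T), dtype=bool)
    if exclude_diagonal:
        np.fill_diagonal(valid, False)

    # The cluster-forming threshold is a symmetric function of the observed
    # map and the permuted maps; leaving the observed map out makes the test
    # slightly anti-conservative with discrete (fold-averaged) accuracies.
    t_all = np.vstack([t_obs.reshape(1, -1), t_null])
    if tail == "one" and alternative == "greater":
        hi = np.quantile(t_all, 1.0 - alpha, axis=0)
        lo = None
    elif tail == "one" and alternative == "less":
        hi = None
        lo = np.quantile(t_all, alpha, axis=0)
    elif tail == "two":
        hi = np.quantile(t_all, 1.0 - alpha / 2.0, axis=0)
        lo = np.quantile(t_all, alpha / 2.0, axis=0)
    else:
        raise ValidationError("tail must be 'one' (greater/less) or 'two'")
    hi2 = hi.reshape(T, T) if hi is not None else None
    lo2 = lo.reshape(T, T) if lo is not None else None

    null_max = np.empty(n_perm)
    for d in range(n_perm):
        cl = _matrix_clusters(t_null[d].reshape(T, T), lo2, hi2, valid)
        null_max[d] = max((abs(s) for _, s in cl), default=0.0)

    clusters = []
    for idx, summed in _matrix_clusters(t_obs, lo2, hi2, valid):
        p = (1.0 + float(np.sum(null_max >= abs(summed)))) / (1.0 + n_perm)
        mean_d = float(np.mean(t_obs[idx]) / np.sqrt(n_subj))
        elements = [tuple(map(int, ij)) for ij in np.argwhere(idx)]
        clusters.append(Cluster(elements=elements, summed_t=summed, p=p, mean_d=mean_d))
    return ClusterResult(clusters=clusters, tail=tail, t_obs=t_obs, alpha=alpha)


def dynamic_elements(
    group_mats: np.ndarray,
    above_chance: ClusterResult,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> DynamicMask:
    """Conjunction test for dynamic coding.

    An off-diagonal element (i, j) is dynamic when a_ij is reliably lower
    than both its diagonal partners — it lies in significant clusters of
    the one-tailed "lower" sign-permutation tests on (a_ij − a_ii) and
    (a_ij − a_jj) — and both partners a_ii, a_jj fall inside above-chance
    clusters.
    """
    X = np.asarray(group_mats, dtype=float)
    n_subj, T, _ = X.shape
    diag = np.einsum("sii->si", X)
    d_train = X - diag[:, :, None]  # a_ij - a_ii
    d_test = X - diag[:, None, :]  # a_ij - a_jj
    ss = np.random.SeedSequence(seed).spawn(2)
    res_train = matrix_cluster_test(
        d_train, chance=0.0, n_perm=n_perm, tail="one", alternative="less",
        alpha=alpha, seed=int(ss[0].generate_state(1)[0] % 2**31), exclude_diagonal=True,
    )
    res_test = matrix_cluster_test(
        d_test, chance=0.0, n_perm=n_perm, tail="one", alternative="less",
        alpha=alpha, seed=int(ss[1].generate_state(1)[0] % 2**31), exclude_diagonal=True,
    )
    above_mask = above_chance.significant_mask(alpha)
    diag_above = np.diag(above_mask)
    mask = res_train.significant_mask(alpha) & res_test.significant_mask(alpha)
    mask &= ~np.eye(T, dtype=bool)
    mask &= diag_above[:, None] & diag_above[None, :]
    return DynamicMask(mask=mask, test_vs_train_diag=res_train, test_vs_test_diag=res_test)


def _interaction_F(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interaction F, SS_interaction and SS_error of a two-way
    fully-within-subject ANOVA; ``y`` has shape (..., subjects, P, L)."""
    S, P, L = y.shape[-3:]
    grand = y.mean(axis=(-3, -2, -1), keepdims=True)
    s_m = y.mean(axis=(-2, -1), keepdims=True)
    p_m = y.mean(axis=(-3, -1), keepdims=True)
    l_m = y.mean(axis=(-3, -2), keepdims=True)
    sp = y.mean(axis=-1, keepdims=True)
    sl = y.mean(axis=-2, keepdims=True)
    pl = y.mean(axis=-3, keepdims=True)
    ss_int = S * np.sum((pl - p_m - l_m + grand) ** 2, axis=(-3, -2, -1))
    resid = y - sp - sl - pl + s_m + p_m + l_m - grand
    ss_err = np.sum(resid**2, axis=(-3, -2, -1))
    df_int = (P - 1) * (L - 1)
    df_err = (S - 1) * df_int
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_int / df_int) / (ss_err / df_err)
    F = np.where(ss_int == 0, 0.0, F)
    F = np.nan_to_num(F, nan=0.0, posinf=_T_CAP)
    return F, ss_int, ss_err


def perm_rm_anova(
    values: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> AnovaResult:
    """Non-parametric repeated-measures ANOVA for the period × layer
    interaction.

    ``values`` is subjects × periods × layers (complete cells). The
    interaction F comes from the standard within-subject decomposition;
    its permutation p-value exchanges the period × layer cell labels within
    each subject; η² = SS_interaction / (SS_interaction + SS_error).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValidationError("values must be subjects x periods x layers")
    if not np.all(np.isfinite(y)):
        raise ValidationError("missing cell in the factorial design")
    S, P, L = y.shape
    F_obs, ss_int, ss_err = _interaction_F(y)
    denom = ss_int + ss_err
    eta_sq = float(ss_int / denom) if denom > 0 else 0.0
    rng = np.random.default_rng(seed)
    flat = y.reshape(S, P * L)
    order = np.argsort(rng.random((n_perm, S, P * L)), axis=2)
    permuted = np.take_along_axis(flat[None, :, :], order, axis=2).reshape(n_perm, S, P, L)
    F_perm, _, _ = _interaction_F(permuted)
    p = (1.0 + float(np.sum(F_perm >= F_obs))) / (1.0 + n_perm)
    return AnovaResult(
        F=float(F_obs), eta_sq=eta_sq, p=p, df=((P - 1) * (L - 1), (S - 1) * (P - 1) * (L - 1))
    )
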
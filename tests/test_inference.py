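"""Permutation inference: nulls, cluster tests, dynamic mask, RM-ANOVA."""

import numpy as np
import pytest

from laminardyn.decoding import TrialTensor, build_folds
from laminardyn.exceptions import ValidationError
from laminardyn.inference import (
    NullDistribution,
    _interaction_F,
    dynamic_elements,
    matrix_cluster_test,
    perm_rm_anova,
    population_null,
    population_null_paired,
    subject_null,
    temporal_cluster_test,
)


def _toy_tensor(seed=0, n=24, v=6, T=3, effect=0.0):
    rng = np.random.default_rng(seed)
    labels = np.array((["a", "a", "b", "b"] * (n // 4)), dtype=object)
    prev = np.roll(labels, 1)
    data = rng.normal(size=(n, v, T))
    if effect:
        pat = rng.normal(size=v)
        data += effect * np.where(labels == "b", 1.0, -1.0)[:, None, None] * pat[:, None]
    return TrialTensor(data=data, labels=labels, prev_labels=prev, times=np.arange(T) * 2.0)


class TestSubjectNull:
    def test_null_mean_near_chance_and_reproducible(self):
        t = _toy_tensor(seed=1)
        folds = build_folds(t.labels, t.prev_labels, seed=0)
        null = subject_null(t, folds, n_perm=25, seed=3)
        assert null.samples.shape == (25, 3)
        assert abs(null.samples.mean() - 0.5) < 0.05
        again = subject_null(t, folds, n_perm=25, seed=3)
        assert np.array_equal(null.samples, again.samples)

    def test_two_seeds_differ_same_distribution(self):
        t = _toy_tensor(seed=2)
        folds = build_folds(t.labels, t.prev_labels, seed=0)
        a = subject_null(t, folds, n_perm=30, seed=1).samples
        b = subject_null(t, folds, n_perm=30, seed=2).samples
        assert not np.array_equal(a, b)
        assert abs(a.mean() - b.mean()) < 0.06  # Monte-Carlo error


class TestPopulationNull:
    def _nulls(self, rng, n_subj=9, n_samp=200, T=6):
        return [
            NullDistribution(rng.binomial(30, 0.5, size=(n_samp, T)) / 30, "subject")
            for _ in range(n_subj)
        ]

    def test_symmetric_nulls_give_zero_mean_t(self):
        rng = np.random.default_rng(0)
        pop = population_null(self._nulls(rng), chance=0.5, n_draws=10_000, seed=1)
        assert pop.samples.shape == (10_000, 6)
        assert abs(pop.samples.mean()) < 0.05

    def test_degenerate_nulls_flagged_as_zero_t(self):
        nulls = [NullDistribution(np.full((50, 4), 0.5), "subject") for _ in range(5)]
        pop = population_null(nulls, chance=0.5, n_draws=100, seed=0)
        assert np.all(pop.samples == 0.0)

    def test_seeded_draws_bit_identical(self):
        rng = np.random.default_rng(3)
        nulls = self._nulls(rng)
        a = population_null(nulls, n_draws=500, seed=7).samples
        b = population_null(nulls, n_draws=500, seed=7).samples
        assert np.array_equal(a, b)

    def test_paired_null_shape_mismatch(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValidationError):
            population_null_paired(self._nulls(rng), self._nulls(rng, T=3), seed=0)


def _chance_pop_null(rng, T, n_subj=9, n_draws=2000):
    nulls = [
        NullDistribution(rng.binomial(30, 0.5, size=(150, T)) / 30, "subject")
        for _ in range(n_subj)
    ]
    return population_null(nulls, chance=0.5, n_draws=n_draws, seed=int(rng.integers(2**31)))


class TestTemporalCluster:
    def test_recovers_injected_cluster_exactly(self):
        rng = np.random.default_rng(0)
        T, n_subj = 10, 9
        # balanced subject offsets: t is exactly 0 off the injected window
        offsets = 0.001 * np.arange(-4, 5)[:, None]
        acc = 0.5 + np.tile(offsets, (1, T))
        acc[:, 4:7] += 0.3  # strong effect at timepoints 4-6 only
        pop = _chance_pop_null(rng, T)
        res = temporal_cluster_test(acc, pop, tail="one")
        assert len(res.clusters) == 1
        assert [e[0] for e in res.clusters[0].elements] == [4, 5, 6]
        assert res.clusters[0].p < 0.01
        assert res.clusters[0].mean_d > 0

    def test_single_point_cluster_allowed(self):
        rng = np.random.default_rng(1)
        T = 8
        acc = 0.5 + 0.01 * rng.standard_normal((9, T))
        acc[:, 3] += 0.3
        res = temporal_cluster_test(acc, _chance_pop_null(rng, T), tail="one")
        assert any(len(c.elements) == 1 and c.elements[0] == (3,) for c in res.clusters)

    def test_null_data_empty_or_insignificant(self):
        rng = np.random.default_rng(123)
        acc = rng.binomial(30, 0.5, size=(9, 12)) / 30
        res = temporal_cluster_test(acc, _chance_pop_null(rng, 12), tail="one")
        assert all(c.p > 0.01 for c in res.clusters)  # no spurious strong cluster

    def test_monotonicity_in_effect_amplitude(self):
        """Noise-free: a larger injected amplitude never shrinks the
        cluster's summed t."""
        rng = np.random.default_rng(5)
        T = 10
        offsets = 0.02 * rng.standard_normal((9, 1))
        bump = np.zeros(T)
        bump[3:6] = 1.0
        pop = _chance_pop_null(rng, T)
        last = 0.0
        for amp in (0.05, 0.1, 0.2, 0.4):
            acc = 0.5 + offsets + amp * bump
            res = temporal_cluster_test(acc, pop, tail="one")
            biggest = max((c.summed_t for c in res.clusters), default=0.0)
            assert biggest >= last - 1e-9
            last = biggest


class TestMatrixCluster:
    def test_block_effect_recovered(self):
        rng = np.random.default_rng(0)
        T, n_subj = 12, 9
        mats = 0.5 + 0.02 * rng.standard_normal((n_subj, T, T))
        mats[:, 2:6, 2:6] += 0.25
        res = matrix_cluster_test(mats, n_perm=800, seed=1)
        sig = res.significant_mask()
        block = np.zeros((T, T), dtype=bool)
        block[2:6, 2:6] = True
        assert (sig & block).sum() >= 0.9 * block.sum()
        assert (sig & ~block).sum() <= 0.05 * (~block).sum()

    def test_null_matrices_do_not_reject(self):
        rng = np.random.default_rng(12)
        mats = rng.binomial(30, 0.5, size=(9, 10, 10)) / 30
        res = matrix_cluster_test(mats, n_perm=800, seed=3)
        assert all(c.p >= 0.05 for c in res.clusters)

    def test_global_sign_flip_preserves_two_tailed_t(self):
        rng = np.random.default_rng(4)
        mats = 0.5 + 0.05 * rng.standard_normal((9, 8, 8))
        a = matrix_cluster_test(mats, tail="two", n_perm=500, seed=5)
        b = matrix_cluster_test(1.0 - mats, tail="two", n_perm=500, seed=5)
        assert np.allclose(np.abs(a.t_obs), np.abs(b.t_obs))

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValidationError):
            matrix_cluster_test(np.full((1, 4, 4), 0.6), n_perm=10, seed=0)


class TestDynamicElements:
    def _matrices(self, rng, T=10, n_subj=9):
        """Block-diagonal structure: two high-accuracy diagonal blocks that
        do not generalize to each other — textbook dynamic coding."""
        mats = 0.5 + 0.02 * rng.standard_normal((n_subj, T, T))
        mats[:, :5, :5] += 0.3
        mats[:, 5:, 5:] += 0.3
        return mats

    def test_dynamic_blocks_found_at_intersections(self):
        rng = np.random.default_rng(0)
        mats = self._matrices(rng)
        above = matrix_cluster_test(mats, n_perm=600, seed=1)
        dyn = dynamic_elements(mats, above, n_perm=600, seed=2)
        assert dyn.mask.any()
        assert not dyn.mask[np.eye(10, dtype=bool)].any()
        # every dynamic element is off-block (between the two coding periods)
        between = np.zeros((10, 10), dtype=bool)
        between[:5, 5:] = between[5:, :5] = True
        assert np.all(between[dyn.mask])

    def test_element_above_its_diagonal_never_dynamic(self):
        rng = np.random.default_rng(3)
        mats = self._matrices(rng)
        above = matrix_cluster_test(mats, n_perm=400, seed=4)
        dyn = dynamic_elements(mats, above, n_perm=400, seed=5)
        mean = mats.mean(axis=0)
        d = np.diag(mean)
        for i, j in np.argwhere(dyn.mask):
            assert mean[i, j] < d[i] and mean[i, j] < d[j]

    def test_stable_generalizing_matrices_give_empty_mask(self):
        rng = np.random.default_rng(6)
        mats = 0.75 + 0.02 * rng.standard_normal((9, 10, 10))  # uniform high
        above = matrix_cluster_test(mats, n_perm=400, seed=7)
        dyn = dynamic_elements(mats, above, n_perm=400, seed=8)
        assert not dyn.mask.any()


class TestPermRmAnova:
    def test_identical_cells_F0_p1(self):
        y = np.tile(np.arange(9.0)[:, None, None], (1, 3, 2))
        res = perm_rm_anova(y, n_perm=200, seed=0)
        assert res.F == 0.0
        assert res.p > 0.99

    def test_interaction_F_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(1)
        y = rng.normal(size=(9, 3, 2))
        F, ss_int, ss_err = _interaction_F(y)
        rows = [
            {"subj": s, "period": p, "layer": l, "y": y[s, p, l]}
            for s in range(9)
            for p in range(3)
            for l in range(2)
        ]
        table = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["period", "layer"],
            subject="subj", detailed=True,
        )
        inter = table[table["Source"].str.contains("\\*")].iloc[0]
        assert float(F) == pytest.approx(inter["F"], rel=1e-9)
        # reconstruct the interaction error SS from pingouin's F and dfs
        ss_err_pg = inter["SS"] / inter["F"] * inter["ddof2"] / inter["ddof1"]
        assert float(ss_int) == pytest.approx(inter["SS"], rel=1e-9)
        assert float(ss_err) == pytest.approx(ss_err_pg, rel=1e-9)

    def test_crossover_interaction_detected(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 0.3, size=(9, 3, 2))
        y[:, 0, 0] += 1.0
        y[:, 2, 1] += 1.0  # crossover
        res = perm_rm_anova(y, n_perm=500, seed=3)
        assert res.p < 0.05
        assert 0.0 <= res.eta_sq <= 1.0

    def test_additive_main_effects_give_uniform_p(self):
        """No interaction: permutation p values are uniform (KS, alpha=0.01)."""
        from scipy import stats

        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            subj = rng.normal(0, 1, size=(9, 1, 1))
            period = rng.normal(0, 1, size=(1, 3, 1))
            layer = rng.normal(0, 1, size=(1, 1, 2))
            y = subj + period + layer + rng.normal(0, 1, size=(9, 3, 2))
            ps.append(perm_rm_anova(y, n_perm=300, seed=int(rng.integers(2**31))).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_cell_rejected(self):
        y = np.ones((9, 3, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            perm_rm_anova(y, n_perm=10, seed=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(9, 3, 2))
        a = perm_rm_anova(y, n_perm=300, seed=11)
        b = perm_rm_anova(y, n_perm=300, seed=11)
        assert a.p == b.p and a.F == b.F
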
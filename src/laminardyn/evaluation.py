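"""End-to-end evaluation suites: calibration and parameter recovery.

These routines exercise the full pipeline on synthetic cohorts with known
ground truth. They are used by the package's acceptance checks and are
available to users as power/calibration tools.

Monte-Carlo problem sizes (40 voxels per layer for decoding suites, 9
subjects, 1,000 sign permutations / population draws, 100 subject-level
null samples) are the package's reduced defaults for confidence-interval
speed; the statistical machinery is identical at full size.
"""

from __future__ import annotations

import logging
import numpy as np

from . import layering
from .containers import VoxelTimeSeries
from .decoding import (
    build_folds,
    concat_tensors,
    cross_decode,
    epoch_trials,
    pair_average,
    preprocess_run,
    trial_normalize,
)
from .design import PERIOD_NAMES, DesignSpec
from .fir import fit_fir, layer_timecourse, to_percent_signal_change
from .inference import (
    dynamic_elements,
    matrix_cluster_test,
    perm_rm_anova,
    population_null,
    population_null_paired,
    temporal_cluster_test,
)
from .synthetic import EffectSpec, NoiseSpec, SubjectData, simulate_cohort
from .univariate import DELAY, condition_contrast, paired_ttest, period_average

logger = logging.getLogger(__name__)

#: hemodynamically shifted decoding-time windows of the three task periods
BOLD_PERIOD_WINDOWS = {
    "encoding": (6.0, 9.7),
    "delay": (9.7, 22.7),
    "retrieval": (22.7, 27.0),
}


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# pipeline fragments
# ---------------------------------------------------------------------------

def layer_tensor(subject: SubjectData, layer: str, run_type: str = "load"):
    """Preprocessed, epoched, pair-averaged, trial-normalized tensor for one
    layer of one subject (runs of ``run_type`` concatenated trial-wise)."""
    rows = layering.layer_voxels(subject.layer_map, layer)
    tensors = []
    for ev, run in zip(subject.events, subject.runs):
        if ev["run_type"].iloc[0] != run_type:
            continue
        sel = VoxelTimeSeries(
            data=run.data[rows], tr_s=run.tr_s, run=run.run, voxel_ids=run.voxel_ids[rows]
        )
        tensors.append(epoch_trials(preprocess_run(sel), ev))
    t = trial_normalize(pair_average(concat_tensors(tensors)))
    t.subject, t.layer = subject.subject, layer
    return t


def cohort_cross_matrices(
    cohort: list[SubjectData], layer: str, seed: int, run_type: str = "load"
) -> np.ndarray:
    """Cross-decoding matrix per subject, stacked (subjects × T × T)."""
    seeds = _child_seeds(seed, len(cohort))
    mats = []
    for subj, s in zip(cohort, seeds):
        t = layer_tensor(subj, layer, run_type)
        folds = build_folds(t.labels, t.prev_labels, seed=s)
        mats.append(cross_decode(t, folds).a)
    return np.stack(mats, axis=0)


def cohort_delay_load_effects(cohort: list[SubjectData]) -> dict[str, np.ndarray]:
    """Per-subject delay-window load effect (high − low PSC) per layer via
    the full FIR + PSC + layer-average path."""
    out: dict[str, list[float]] = {"superficial": [], "deep": []}
    for subj in cohort:
        load = [
            (run, ev)
            for run, ev in zip(subj.runs, subj.events)
            if ev["run_type"].iloc[0] == "load"
        ]
        est = fit_fir([r for r, _ in load], [e for _, e in load], conditions=["high", "low"])
        tc = layer_timecourse(to_percent_signal_change(est), subj.layer_map, subject=subj.subject)
        eff = period_average(condition_contrast(tc, "high", "low"), DELAY)
        for layer in out:
            out[layer].append(eff[layer])
    return {k: np.array(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# recovery suites
# ---------------------------------------------------------------------------

def univariate_recovery_rate(
    n_cohorts: int = 50,
    amp: float = 0.2,
    seed: int = 0,
    n_subjects: int = 9,
    n_voxels_per_layer: int = 40,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulated cohorts in which a superficial-only delay load
    amplitude yields a significant superficial-vs-deep paired test.
    With ``amp=0`` this is the test's empirical type-I error."""
    spec = DesignSpec(n_runs_load=2, n_runs_motor=0)
    effects = EffectSpec(amplitudes={("superficial", "high", "delay"): amp})
    noise = NoiseSpec()
    hits = 0
    for cs in _child_seeds(seed, n_cohorts):
        cohort = simulate_cohort(
            spec, effects, noise, n_subjects=n_subjects,
            n_voxels_per_layer=n_voxels_per_layer, seed=cs,
        )
        eff = cohort_delay_load_effects(cohort)
        res = paired_ttest(eff["superficial"], eff["deep"])
        hits += res.p < alpha
    return hits / n_cohorts


def _between_period_template(times: np.ndarray) -> np.ndarray:
    """(i, j) mask of train/test timepoint pairs falling in two *different*
    task periods (hemodynamically shifted windows)."""
    period = np.array(
        [
            next(
                (name for name, (a, b) in BOLD_PERIOD_WINDOWS.items() if a <= t < b),
                "none",
            )
            for t in times
        ]
    )
    known = period != "none"
    diff = period[:, None] != period[None, :]
    return diff & known[:, None] & known[None, :]


def dynamic_mask_rates(
    n_cohorts: int = 50,
    dynamics: str = "dynamic",
    pattern_amp: float = 0.45,
    seed: int = 0,
    n_subjects: int = 9,
    n_voxels_per_layer: int = 40,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Dynamic-coding detection rates over simulated cohorts.

    With ``dynamics="dynamic"`` (period-orthogonal patterns) returns the
    fraction of cohorts whose dynamic mask is nonempty at between-period
    train/test intersections; with ``"stable"`` the fraction with *any*
    dynamic element (the false-positive cohort rate).
    """
    spec = DesignSpec(n_runs_load=2, n_runs_motor=0)
    effects = EffectSpec(
        pattern_amplitudes={
            ("superficial", cond, period): pattern_amp
            for cond in ("high", "low")
            for period in PERIOD_NAMES
        },
        pattern_dynamics=dynamics,
    )
    noise = NoiseSpec()
    hits_between, hits_any = 0, 0
    template = None
    for cs in _child_seeds(seed, n_cohorts):
        s_sim, s_fold, s_above, s_dyn = _child_seeds(cs, 4)
        cohort = simulate_cohort(
            spec, effects, noise, n_subjects=n_subjects,
            n_voxels_per_layer=n_voxels_per_layer, seed=s_sim,
        )
        mats = cohort_cross_matrices(cohort, "superficial", seed=s_fold)
        if template is None:
            times = layer_tensor(cohort[0], "superficial").times
            template = _between_period_template(times)
        above = matrix_cluster_test(
            mats, chance=0.5, n_perm=n_perm, tail="one", alternative="greater",
            alpha=alpha, seed=s_above,
        )
        dyn = dynamic_elements(mats, above, n_perm=n_perm, alpha=alpha, seed=s_dyn)
        hits_any += bool(dyn.mask.any())
        hits_between += bool((dyn.mask & template).any())
    return {
        "between_period_rate": hits_between / n_cohorts,
        "any_dynamic_rate": hits_any / n_cohorts,
    }


# ---------------------------------------------------------------------------
# calibration (type-I error) of the permutation tests
# ---------------------------------------------------------------------------

def _null_accuracy_cohort(
    rng: np.random.Generator,
    n_subjects: int,
    n_timepoints: int,
    n_trials: int,
    n_subject_samples: int,
):
    """Exchangeable null decoding accuracies: the empirical per-subject
    accuracies and each subject's null distribution are draws from the same
    binomial chance process."""
    emp = rng.binomial(n_trials, 0.5, size=(n_subjects, n_timepoints)) / n_trials
    nulls = [
        rng.binomial(n_trials, 0.5, size=(n_subject_samples, n_timepoints)) / n_trials
        for _ in range(n_subjects)
    ]
    return emp, nulls


def calibration_rates(
    n_cohorts: int = 200,
    seed: int = 0,
    n_subjects: int = 9,
    n_timepoints: int = 16,
    n_trials: int = 30,
    n_subject_samples: int = 100,
    n_draws: int = 1000,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Empirical familywise type-I error of every permutation test at
    nominal ``alpha`` over exchangeable null cohorts.

    Covers the 1-D above-chance cluster test, the two-tailed paired layer
    comparison, the 2-D sign-permutation matrix cluster test and the
    permutation repeated-measures ANOVA (reduced permutation counts for
    confidence-interval speed).
    """
    rej = {"temporal_above_chance": 0, "temporal_layer_paired": 0, "matrix": 0, "rm_anova": 0}
    for cs in _child_seeds(seed, n_cohorts):
        rng = np.random.default_rng(cs)
        s_pop, s_pop2, s_mat, s_anova = _child_seeds(cs ^ 0x5A5A5A, 4)

        emp, nulls = _null_accuracy_cohort(
            rng, n_subjects, n_timepoints, n_trials, n_subject_samples
        )
        pop = population_null(nulls, chance=0.5, n_draws=n_draws, seed=s_pop)
        res = temporal_cluster_test(emp, pop, tail="one", alpha=alpha)
        rej["temporal_above_chance"] += any(c.p < alpha for c in res.clusters)

        emp2, nulls2 = _null_accuracy_cohort(
            rng, n_subjects, n_timepoints, n_trials, n_subject_samples
        )
        pop_pair = population_null_paired(nulls, nulls2, n_draws=n_draws, seed=s_pop2)
        res2 = temporal_cluster_test(emp - emp2, pop_pair, tail="two", alpha=alpha, chance=0.0)
        rej["temporal_layer_paired"] += any(c.p < alpha for c in res2.clusters)

        mats = rng.binomial(n_trials, 0.5, size=(n_subjects, n_timepoints, n_timepoints)) / n_trials
        res3 = matrix_cluster_test(
            mats, chance=0.5, n_perm=n_perm, tail="one", alternative="greater",
            alpha=alpha, seed=s_mat,
        )
        rej["matrix"] += any(c.p < alpha for c in res3.clusters)

        y = rng.standard_normal((n_subjects, 3, 2))
        res4 = perm_rm_anova(y, n_perm=n_perm, seed=s_anova)
        rej["rm_anova"] += res4.p < alpha
    return {k: v / n_cohorts for k, v in rej.items()}
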
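"""Pipeline orchestration: simulate → layers → FIR → univariate → decode →
cross-decode → permutation stats → report, driven by one config."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import layering
from .decoding import build_folds, decode_timecourse
from .design import DesignSpec
from .evaluation import (
    BOLD_PERIOD_WINDOWS,
    _child_seeds,
    cohort_cross_matrices,
    layer_tensor,
)
from .exceptions import ValidationError
from .fir import fit_fir, layer_timecourse, to_percent_signal_change
from .inference import (
    dynamic_elements,
    matrix_cluster_test,
    perm_rm_anova,
    population_null,
    population_null_paired,
    subject_null,
    temporal_cluster_test,
)
from .synthetic import (
    EffectSpec,
    NoiseSpec,
    SubjectData,
    default_effects,
    read_fixture,
    simulate_cohort,
)
from .univariate import DELAY, RETRIEVAL, condition_contrast, paired_ttest, period_average

logger = logging.getLogger(__name__)

ANALYZED_LAYERS = ("superficial", "deep")

CONTRAST_CONDITIONS = {"load": ("high", "low"), "motor": ("response", "abstain")}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    mode: str = "simulate"  # "simulate" | "external"
    contrast: str = "load"
    out: str = "out"
    external_subjects: list[str] = field(default_factory=list)
    seed: int = 0
    # decoding parameters
    cost: float = 1.0
    hp_cutoff_s: float = 128.0
    n_trs: int = 17
    # permutation parameters
    n_subject_perm: int = 250
    n_population_draws: int = 10_000
    n_matrix_perm: int = 10_000
    alpha: float = 0.05
    # simulation block
    n_subjects: int = 9
    n_voxels_per_layer: int = 200
    pattern_dynamics: str = "dynamic"
    noise_sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_order: int = 3
    drift_scale: float = 1.0
    subject_amp_sd: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.contrast not in CONTRAST_CONDITIONS:
            raise ValidationError("contrast must be 'load' or 'motor'")
        if self.mode not in ("simulate", "external"):
            raise ValidationError("mode must be 'simulate' or 'external'")
        if self.mode == "external":
            missing = [p for p in self.external_subjects if not Path(p).exists()]
            if not self.external_subjects or missing:
                raise ValidationError(f"external mode needs existing subject paths; missing {missing}")
        for name in ("n_subject_perm", "n_population_draws", "n_matrix_perm", "n_trs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _get_cohort(config: PipelineConfig) -> list[SubjectData]:
    if config.mode == "external":
        return [read_fixture(p) for p in config.external_subjects]
    noise = NoiseSpec(
        sigma=config.noise_sigma,
        ar1_rho=config.ar1_rho,
        drift_order=config.drift_order,
        drift_scale=config.drift_scale,
    )
    return simulate_cohort(
        DesignSpec(),
        default_effects(config.pattern_dynamics),
        noise,
        n_subjects=config.n_subjects,
        n_voxels_per_layer=config.n_voxels_per_layer,
        seed=config.seed,
        subject_amp_sd=config.subject_amp_sd,
    )


def _univariate_stage(cohort: list[SubjectData]) -> dict:
    """Layer timecourses, load/motor effects and paired layer tests."""
    eff = {
        ("load", p.label): {l: [] for l in ANALYZED_LAYERS} for p in (DELAY, RETRIEVAL)
    }
    eff[("motor", "retrieval")] = {l: [] for l in ANALYZED_LAYERS}
    curves: dict = {}
    for subj in cohort:
        for run_type, (a, b) in CONTRAST_CONDITIONS.items():
            runs = [
                (r, e)
                for r, e in zip(subj.runs, subj.events)
                if e["run_type"].iloc[0] == run_type
            ]
            if not runs:
                continue
            est = fit_fir([r for r, _ in runs], [e for _, e in runs], conditions=[a, b])
            tc = layer_timecourse(
                to_percent_signal_change(est), subj.layer_map, subject=subj.subject
            )
            for key, curve in tc.values.items():
                curves.setdefault(key, []).append(curve)
            contrast = condition_contrast(tc, a, b)
            periods = (DELAY, RETRIEVAL) if run_type == "load" else (RETRIEVAL,)
            for period in periods:
                by_layer = period_average(contrast, period)
                for layer in ANALYZED_LAYERS:
                    eff[(run_type, period.label)][layer].append(by_layer[layer])
    tests = {}
    for (run_type, period), by_layer in eff.items():
        sup = np.array(by_layer["superficial"])
        deep = np.array(by_layer["deep"])
        if sup.size < 2:
            continue
        res = paired_ttest(sup, deep)
        tests[f"{run_type}_{period}"] = {
            "t": res.t, "df": res.df, "p": res.p,
            "ci95": list(res.ci95), "d": res.d,
            "mean_superficial": float(sup.mean()), "mean_deep": float(deep.mean()),
        }
    mean_curves = {
        f"{layer}/{cond}": np.mean(np.stack(v), axis=0).tolist()
        for (layer, cond), v in curves.items()
    }
    return {"tests": tests, "mean_timecourses": mean_curves, "effects": {
        f"{rt}_{p}": {l: list(map(float, v)) for l, v in d.items()} for (rt, p), d in eff.items()
    }}


def _decoding_stage(cohort: list[SubjectData], config: PipelineConfig) -> dict:
    """Per-layer decoding timecourses, subject nulls and cross matrices."""
    run_type = config.contrast
    out: dict = {"accuracy": {}, "nulls": {}, "matrices": {}, "times": None}
    seeds = _child_seeds(config.seed ^ 0x0DEC0DE, 2 * len(cohort) + 1)
    for layer in ANALYZED_LAYERS:
        accs, nulls = [], []
        for i, subj in enumerate(cohort):
            t = layer_tensor(subj, layer, run_type)
            folds = build_folds(t.labels, t.prev_labels, seed=seeds[i])
            tc = decode_timecourse(t, folds, cost=config.cost)
            accs.append(tc.accuracy)
            nulls.append(
                subject_null(
                    t, folds, n_perm=config.n_subject_perm,
                    seed=seeds[len(cohort) + i], cost=config.cost,
                )
            )
            out["times"] = tc.times.tolist()
        out["accuracy"][layer] = np.stack(accs)
        out["nulls"][layer] = nulls
        out["matrices"][layer] = cohort_cross_matrices(
            cohort, layer, seed=seeds[-1], run_type=run_type
        )
    return out


def _stats_stage(dec: dict, config: PipelineConfig) -> dict:
    alpha = config.alpha
    seeds = _child_seeds(config.seed ^ 0x57A75, 8)
    results: dict = {"temporal": {}, "matrix": {}, "dynamic": {}, "anova": None}

    def cluster_dicts(res):
        return [
            {"elements": c.elements, "summed_t": c.summed_t, "p": c.p, "mean_d": c.mean_d}
            for c in res.clusters
        ]

    for k, layer in enumerate(ANALYZED_LAYERS):
        pop = population_null(
            dec["nulls"][layer], chance=0.5,
            n_draws=config.n_population_draws, seed=seeds[k],
        )
        res = temporal_cluster_test(dec["accuracy"][layer], pop, tail="one", alpha=alpha)
        results["temporal"][layer] = cluster_dicts(res)
        mres = matrix_cluster_test(
            dec["matrices"][layer], chance=0.5, n_perm=config.n_matrix_perm,
            tail="one", alternative="greater", alpha=alpha, seed=seeds[2 + k],
        )
        results["matrix"][layer] = cluster_dicts(mres)
        dyn = dynamic_elements(
            dec["matrices"][layer], mres, n_perm=config.n_matrix_perm,
            alpha=alpha, seed=seeds[4 + k],
        )
        results["dynamic"][layer] = {
            "n_elements": int(dyn.mask.sum()),
            "elements": [tuple(map(int, ij)) for ij in np.argwhere(dyn.mask)],
        }

    pop_pair = population_null_paired(
        dec["nulls"]["superficial"], dec["nulls"]["deep"],
        n_draws=config.n_population_draws, seed=seeds[6],
    )
    diff = dec["accuracy"]["superficial"] - dec["accuracy"]["deep"]
    res = temporal_cluster_test(diff, pop_pair, tail="two", alpha=alpha, chance=0.0)
    results["temporal"]["superficial_vs_deep"] = cluster_dicts(res)

    # period x layer interaction on period-averaged accuracies
    times = np.array(dec["times"])
    cells = []
    for layer in ANALYZED_LAYERS:
        acc = dec["accuracy"][layer]
        per = []
        for a, b in BOLD_PERIOD_WINDOWS.values():
            sel = (times >= a) & (times < b)
            per.append(acc[:, sel].mean(axis=1))
        cells.append(np.stack(per, axis=1))  # subjects x periods
    y = np.stack(cells, axis=2)  # subjects x periods x layers
    ares = perm_rm_anova(y, n_perm=config.n_population_draws, seed=seeds[7])
    results["anova"] = {"F": ares.F, "eta_sq": ares.eta_sq, "p": ares.p, "df": list(ares.df)}
    return results


def _figures(univ: dict, dec: dict, out_dir: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    knots = np.arange(2, 31, 2)
    fig, axes = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    for ax, layer in zip(axes, ANALYZED_LAYERS):
        for key, curve in univ["mean_timecourses"].items():
            if key.startswith(layer):
                ax.plot(knots, curve, label=key.split("/")[1])
        ax.set_ylabel(f"{layer} PSC (%)")
        ax.legend(fontsize=7)
    axes[-1].set_xlabel("time after trial onset (s)")
    p = out_dir / "fig_timecourses.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    made.append(p.name)

    times = dec["times"]
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, layer in zip(axes[:2], ANALYZED_LAYERS):
        acc = dec["accuracy"][layer]
        ax.plot(times, acc.mean(axis=0))
        ax.axhline(0.5, color="gray", lw=0.5)
        ax.set_title(f"{layer} decoding")
        ax.set_xlabel("time (s)")
    im = axes[2].imshow(
        dec["matrices"]["superficial"].mean(axis=0), origin="lower",
        extent=[times[0], times[-1], times[0], times[-1]], vmin=0.3, vmax=0.9,
        cmap="viridis",
    )
    axes[2].set_title("superficial cross-decoding")
    axes[2].set_xlabel("test time (s)")
    axes[2].set_ylabel("train time (s)")
    fig.colorbar(im, ax=axes[2], shrink=0.8)
    p = out_dir / "fig_decoding.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    made.append(p.name)
    return made


def run_pipeline(config: PipelineConfig, write_figures: bool = True) -> dict:
    """Run every stage; write results JSON/TSVs (and figures) to
    ``config.out``; return the results dict. Deterministic given the seed."""
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("stage: data (%s)", config.mode)
    cohort = _get_cohort(config)

    logger.info("stage: layers")
    balance = layering.check_layer_balance([s.layer_map for s in cohort])
    balance.to_csv(out_dir / "layer_balance.tsv", sep="\t")

    logger.info("stage: univariate")
    univ = _univariate_stage(cohort)
    rows = []
    for name, r in univ["tests"].items():
        rows.append({"test": name, **{k: r[k] for k in ("t", "df", "p", "d")},
                     "ci_low": r["ci95"][0], "ci_high": r["ci95"][1]})
    pd.DataFrame(rows).to_csv(out_dir / "univariate_tests.tsv", sep="\t", index=False)

    logger.info("stage: decoding")
    dec = _decoding_stage(cohort, config)
    for layer in ANALYZED_LAYERS:
        pd.DataFrame(
            dec["accuracy"][layer], columns=[f"t{t:g}" for t in dec["times"]]
        ).to_csv(out_dir / f"accuracy_{layer}.tsv", sep="\t", index_label="subject")
        np.savetxt(
            out_dir / f"crossdecoding_{layer}_mean.tsv",
            dec["matrices"][layer].mean(axis=0), delimiter="\t",
        )

    logger.info("stage: stats")
    stats = _stats_stage(dec, config)

    results = {
        "config": asdict(config),
        "layer_balance": balance.reset_index().to_dict(orient="records"),
        "univariate": {"tests": univ["tests"]},
        "decoding": {
            "times": dec["times"],
            "mean_accuracy": {
                l: dec["accuracy"][l].mean(axis=0).tolist() for l in ANALYZED_LAYERS
            },
        },
        "stats": stats,
    }
    (out_dir / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    if write_figures:
        logger.info("stage: report")
        results["figures"] = _figures(univ, dec, out_dir)
    return results
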
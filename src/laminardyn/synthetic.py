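"""Synthetic laminar BOLD generator.

Emulates the structure of a laminar working-memory fMRI session: 4 runs x
16 trials of 30.7 s (TR = 2 s), two conditions per run type, three depth
bins per ROI with condition-dependent univariate amplitudes and multivariate
patterns per trial period, AR(1)-correlated noise, slow polynomial drift,
and optional deep-to-superficial signal leakage (a linear draining-vein
model). Every injected effect is recorded in a ground-truth dictionary so
downstream stages can be tested by parameter recovery.

Units: the default baseline is 100, so one raw signal unit equals one
percent signal change (PSC). Amplitudes, noise ``sigma`` and drift scale are
all expressed on that scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import VoxelTimeSeries
from .design import PERIOD_NAMES, DesignSpec, generate_design
from .exceptions import ConstraintError, ValidationError
from . import layering

logger = logging.getLogger(__name__)

LAYERS = ("deep", "middle", "superficial")
LAYER_CODES = {"deep": 1, "middle": 2, "superficial": 3}

_FINE_DT = 0.1  # seconds; fine grid for boxcar-HRF convolution


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: AR(1) temporal noise plus polynomial drift.

    ``sigma`` is the marginal SD of the AR(1) process (PSC units),
    ``ar1_rho`` its lag-1 autocorrelation, ``drift_scale`` the SD of the
    random coefficients on orthogonal polynomial drift terms of order
    1..``drift_order``.
    """

    sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_order: int = 3
    drift_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise ValidationError("|ar1_rho| must be < 1")
        if self.drift_order < 0:
            raise ValidationError("drift_order must be >= 0")


@dataclass
class EffectSpec:
    """Ground-truth effects to inject.

    ``amplitudes`` maps (layer, condition, period) to a univariate PSC
    amplitude added uniformly to every voxel of the layer;
    ``pattern_amplitudes`` maps the same keys to the per-voxel RMS amplitude
    of a multivariate pattern. With ``pattern_dynamics="stable"`` a
    condition keeps one pattern across all periods; with ``"dynamic"`` each
    period gets its own near-orthogonal pattern. ``leakage_lambda`` mixes
    the deep-layer signal into the superficial layer (before noise).
    """

    amplitudes: dict[tuple[str, str, str], float] = field(default_factory=dict)
    pattern_amplitudes: dict[tuple[str, str, str], float] = field(default_factory=dict)
    pattern_dynamics: str = "stable"
    leakage_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern_dynamics not in ("stable", "dynamic"):
            raise ValidationError("pattern_dynamics must be 'stable' or 'dynamic'")
        if not 0.0 <= self.leakage_lambda < 1.0:
            raise ValidationError("leakage_lambda must be in [0, 1)")
        for table in (self.amplitudes, self.pattern_amplitudes):
            for key, a in table.items():
                if len(key) != 3:
                    raise ValidationError(f"effect key {key!r} is not (layer, condition, period)")
                if key[0] not in LAYERS:
                    raise ValidationError(f"unknown layer {key[0]!r}")
                if key[2] not in PERIOD_NAMES:
                    raise ValidationError(f"unknown period {key[2]!r}")
                if not np.isfinite(a):
                    raise ValidationError(f"amplitude for {key!r} is not finite")

    def pattern_id(self, layer: str, condition: str, period: str) -> str:
        if self.pattern_dynamics == "stable":
            return f"{layer}:{condition}"
        return f"{layer}:{condition}:{period}"

    def pattern_ids(self) -> dict[str, str]:
        """Map every nonzero pattern key to its pattern id."""
        return {
            f"{k[0]}:{k[1]}:{k[2]}": self.pattern_id(*k)
            for k, a in self.pattern_amplitudes.items()
            if a != 0.0
        }


def double_gamma_hrf(dt: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot
    16 s, peak:undershoot ratio 6), normalized to unit peak."""
    from scipy.stats import gamma

    t = np.arange(0.0, duration_s, dt)
    h = gamma.pdf(t, a=6.0, scale=1.0) - gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def generate_patterns(
    n_voxels_per_layer: int,
    effects: EffectSpec,
    seed: int,
    max_resample: int = 1000,
    max_abs_cos: float = 0.3,
) -> dict[str, np.ndarray]:
    """Draw one unit-norm voxel pattern per pattern id.

    In dynamic mode, patterns sharing a layer are resampled until all
    pairwise |cosine| similarities are below ``max_abs_cos`` (raises after
    ``max_resample`` attempts). In stable mode all periods of a condition
    reference the same vector by construction.
    """
    if n_voxels_per_layer < 2:
        raise ValidationError("n_voxels_per_layer must be >= 2")
    rng = np.random.default_rng(seed)
    ids = sorted(set(effects.pattern_ids().values()))
    patterns: dict[str, np.ndarray] = {}
    for pid in ids:
        layer = pid.split(":")[0]
        peers = [p for q, p in patterns.items() if q.split(":")[0] == layer]
        for attempt in range(max_resample):
            v = rng.standard_normal(n_voxels_per_layer)
            v /= np.linalg.norm(v)
            if all(abs(float(v @ p)) < max_abs_cos for p in peers):
                patterns[pid] = v
                break
        else:
            raise ConstraintError(
                f"could not draw pattern {pid!r} with pairwise |cos| < {max_abs_cos} "
                f"in {max_resample} resamples"
            )
    return patterns


def layer_slices(n_voxels_per_layer: int) -> dict[str, slice]:
    """Voxel row ranges per layer: deep, middle, superficial stacked."""
    n = n_voxels_per_layer
    return {
        "deep": slice(0, n),
        "middle": slice(n, 2 * n),
        "superficial": slice(2 * n, 3 * n),
    }


def _period_regressor(
    onsets: np.ndarray, window: tuple[float, float], spec: DesignSpec, hrf: np.ndarray
) -> np.ndarray:
    """Boxcar over ``window`` (s post-onset) for each onset, convolved with
    the HRF on a fine grid, sampled at TR times.

    The regressor is scaled so a *single trial's* response peaks at 1;
    injected amplitudes are therefore per-trial peak PSC, directly
    comparable to FIR tent estimates.
    """
    n_fine = int(round(spec.run_duration_s / _FINE_DT))
    box = np.zeros(n_fine)
    for onset in onsets:
        i0 = int(round((onset + window[0]) / _FINE_DT))
        i1 = int(round((onset + window[1]) / _FINE_DT))
        box[i0 : min(i1, n_fine)] += 1.0
    conv = np.convolve(box, hrf)[:n_fine]
    # single-event response peak used as the normalization constant
    n_box = max(int(round((window[1] - window[0]) / _FINE_DT)), 1)
    peak = np.convolve(np.ones(n_box), hrf).max()
    scan_idx = np.round(np.arange(spec.n_scans) * spec.tr_s / _FINE_DT).astype(int)
    scan_idx = np.clip(scan_idx, 0, n_fine - 1)
    return conv[scan_idx] / peak


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], noise: NoiseSpec) -> np.ndarray:
    if noise.sigma == 0:
        return np.zeros(shape)
    innov_sd = noise.sigma * np.sqrt(1.0 - noise.ar1_rho**2)
    white = rng.standard_normal(shape) * innov_sd
    return sps.lfilter([1.0], [1.0, -noise.ar1_rho], white, axis=1)


def _drift(rng: np.random.Generator, n_voxels: int, n_scans: int, noise: NoiseSpec) -> np.ndarray:
    if noise.drift_order < 1 or noise.drift_scale == 0:
        return np.zeros((n_voxels, n_scans))
    x = np.linspace(-1.0, 1.0, n_scans)
    basis = np.polynomial.legendre.legvander(x, noise.drift_order)[:, 1:]
    coefs = rng.standard_normal((n_voxels, basis.shape[1])) * noise.drift_scale
    return coefs @ basis.T


def simulate_run(
    events: pd.DataFrame,
    patterns: dict[str, np.ndarray],
    effects: EffectSpec,
    noise: NoiseSpec,
    spec: DesignSpec,
    n_voxels_per_layer: int = 200,
    baseline: float = 100.0,
    seed: int | None = None,
) -> tuple[VoxelTimeSeries, dict]:
    """Simulate one run for all three layers.

    Signal is the sum over trials and periods of
    ``amplitude(layer, condition, period) x pattern x (period boxcar * HRF)``
    sampled at TRs; superficial voxels then receive ``leakage_lambda`` times
    the deep signal; AR(1) noise and polynomial drift are added on top of
    the baseline. Returns the time series and a ground-truth record.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    windows = spec.period_windows()
    for name, (_, p_end) in windows.items():
        if p_end > spec.trial_duration_s + 1e-9:
            raise ValidationError(f"period {name!r} extends past the trial window")
    last_end = events["onset_s"].max() + spec.trial_duration_s
    if last_end > spec.run_duration_s + 1e-6:
        raise ValidationError("events extend past the run length")
    if not events["onset_s"].is_monotonic_increasing:
        raise ValidationError("onsets must be strictly increasing within a run")

    n = n_voxels_per_layer
    slices = layer_slices(n)
    hrf = double_gamma_hrf(_FINE_DT)
    n_scans = spec.n_scans
    sig = np.zeros((3 * n, n_scans))

    keys = set(effects.amplitudes) | set(effects.pattern_amplitudes)
    reg_cache: dict[tuple[str, str], np.ndarray] = {}
    for layer, cond, period in sorted(keys):
        uni = effects.amplitudes.get((layer, cond, period), 0.0)
        pat_amp = effects.pattern_amplitudes.get((layer, cond, period), 0.0)
        if uni == 0.0 and pat_amp == 0.0:
            continue
        ck = (cond, period)
        if ck not in reg_cache:
            onsets = events.loc[events["condition"] == cond, "onset_s"].to_numpy()
            reg_cache[ck] = _period_regressor(onsets, windows[period], spec, hrf)
        vec = np.full(n, uni)
        if pat_amp != 0.0:
            pid = effects.pattern_id(layer, cond, period)
            # unit-norm pattern scaled so pat_amp is the per-voxel RMS amplitude
            vec = vec + pat_amp * np.sqrt(n) * patterns[pid]
        sig[slices[layer]] += np.outer(vec, reg_cache[ck])

    if effects.leakage_lambda != 0.0:
        sig[slices["superficial"]] += effects.leakage_lambda * sig[slices["deep"]]

    data = (
        baseline
        + sig
        + _drift(rng, 3 * n, n_scans, noise)
        + _ar1_noise(rng, (3 * n, n_scans), noise)
    )
    run_id = int(events["run"].iloc[0]) if len(events) else 0
    ts = VoxelTimeSeries(data=data, tr_s=spec.tr_s, run=run_id)
    truth = {
        "run": run_id,
        "baseline": baseline,
        "amplitudes": {"/".join(k): v for k, v in effects.amplitudes.items()},
        "pattern_amplitudes": {"/".join(k): v for k, v in effects.pattern_amplitudes.items()},
        "pattern_ids": effects.pattern_ids(),
        "pattern_dynamics": effects.pattern_dynamics,
        "leakage_lambda": effects.leakage_lambda,
        "regressors": {"/".join(k): v.tolist() for k, v in reg_cache.items()},
    }
    return ts, truth


@dataclass
class SubjectData:
    """One simulated participant: events and data per run plus ground truth."""

    subject: str
    spec: DesignSpec
    events: list[pd.DataFrame]
    runs: list[VoxelTimeSeries]
    layer_map: pd.DataFrame
    truth: dict


def _synthetic_depths(n_voxels_per_layer: int, rng: np.random.Generator) -> np.ndarray:
    """Cortical depths (0 = white-matter surface, 1 = pial) that land each
    stacked voxel block in its intended equidistant bin."""
    n = n_voxels_per_layer
    depths = np.concatenate(
        [(k + rng.uniform(0.0, 1.0, n)) / 3.0 for k in range(3)]
    )
    return np.clip(depths, 0.0, np.nextafter(1.0, 0.0))


def simulate_subject(
    spec: DesignSpec,
    effects: EffectSpec,
    noise: NoiseSpec,
    n_voxels_per_layer: int = 200,
    seed: int = 0,
    subject: str = "S01",
    roi: str = "dlPFC",
    baseline: float = 100.0,
) -> SubjectData:
    """Simulate a full session (all runs) for one participant."""
    ss = np.random.SeedSequence(seed)
    design_seed, pattern_seed, depth_seed, *run_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 + spec.n_runs)
    ]
    events = generate_design(spec, design_seed)
    patterns = generate_patterns(n_voxels_per_layer, effects, pattern_seed)
    depths = _synthetic_depths(n_voxels_per_layer, np.random.default_rng(depth_seed))
    layer_map = layering.assign_layers(depths, roi=roi)
    runs, run_truths = [], []
    for ev, rs in zip(events, run_seeds):
        ts, tr = simulate_run(
            ev, patterns, effects, noise, spec,
            n_voxels_per_layer=n_voxels_per_layer, baseline=baseline, seed=rs,
        )
        runs.append(ts)
        run_truths.append(tr)
    truth = {
        "subject": subject,
        "patterns": {k: v.tolist() for k, v in patterns.items()},
        "runs": run_truths,
        "effects": run_truths[0] if run_truths else {},
    }
    return SubjectData(
        subject=subject, spec=spec, events=events, runs=runs,
        layer_map=layer_map, truth=truth,
    )


def simulate_cohort(
    spec: DesignSpec,
    effects: EffectSpec,
    noise: NoiseSpec,
    n_subjects: int = 9,
    n_voxels_per_layer: int = 200,
    seed: int = 0,
    subject_amp_sd: float = 0.25,
) -> list[SubjectData]:
    """Simulate a cohort; per-subject multiplicative amplitude variability
    (lognormal-like, SD ``subject_amp_sd``) models between-participant
    differences in effect size."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    rng = np.random.default_rng(int(ss.generate_state(1)[0] % (2**31)))
    cohort = []
    for i, child in enumerate(children):
        gain = float(max(0.05, 1.0 + subject_amp_sd * rng.standard_normal()))
        eff_i = replace(
            effects,
            amplitudes={k: v * gain for k, v in effects.amplitudes.items()},
            pattern_amplitudes={k: v * gain for k, v in effects.pattern_amplitudes.items()},
        )
        cohort.append(
            simulate_subject(
                spec, eff_i, noise,
                n_voxels_per_layer=n_voxels_per_layer,
                seed=int(child.generate_state(1)[0] % (2**31)),
                subject=f"S{i + 1:02d}",
            )
        )
    return cohort


def default_effects(pattern_dynamics: str = "dynamic") -> EffectSpec:
    """Study-condition-like default effects.

    Univariate amplitudes follow the printed scale of the layer timecourses
    (load effects of ~0.1-0.2 PSC, larger superficially during the delay);
    pattern amplitudes are set so group decoding accuracy peaks around
    0.6-0.75 at the default noise level.
    """
    amplitudes: dict[tuple[str, str, str], float] = {}
    for layer, gain in (("superficial", 1.0), ("deep", 0.7)):
        amplitudes[(layer, "high", "encoding")] = 0.45 * gain
        amplitudes[(layer, "low", "encoding")] = 0.40 * gain
        amplitudes[(layer, "high", "delay")] = 0.30 * gain
        amplitudes[(layer, "low", "delay")] = (0.30 - 0.15 * gain) * gain
        amplitudes[(layer, "high", "retrieval")] = 0.45 * gain
        amplitudes[(layer, "low", "retrieval")] = 0.35 * gain
        # motor runs: strong response-locked retrieval activity in both layers
        amplitudes[(layer, "response", "retrieval")] = 0.50
        amplitudes[(layer, "abstain", "retrieval")] = 0.10
        for cond in ("response", "abstain"):
            amplitudes[(layer, cond, "encoding")] = 0.40
            amplitudes[(layer, cond, "delay")] = 0.25
    pattern_amplitudes: dict[tuple[str, str, str], float] = {}
    for cond in ("high", "low"):
        for period in PERIOD_NAMES:
            pattern_amplitudes[("superficial", cond, period)] = 0.45
            pattern_amplitudes[("deep", cond, period)] = 0.30
    for cond in ("response", "abstain"):
        pattern_amplitudes[("superficial", cond, "retrieval")] = 0.40
        pattern_amplitudes[("deep", cond, "retrieval")] = 0.40
    return EffectSpec(
        amplitudes=amplitudes,
        pattern_amplitudes=pattern_amplitudes,
        pattern_dynamics=pattern_dynamics,
    )


# ---------------------------------------------------------------------------
# fixture I/O (NIfTI + BIDS-style events TSV + ground-truth JSON)
# ---------------------------------------------------------------------------

def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    nx = int(np.ceil(np.sqrt(n_voxels)))
    ny = int(np.ceil(n_voxels / nx))
    return nx, ny, 1


def _to_grid(flat: np.ndarray, n_voxels: int) -> np.ndarray:
    """Place voxel rows on a dummy 3-D grid (+ time if 2-D input)."""
    nx, ny, nz = _grid_shape(n_voxels)
    extra = flat.shape[1:] if flat.ndim > 1 else ()
    out = np.zeros((nx * ny * nz, *extra), dtype=flat.dtype)
    out[:n_voxels] = flat
    return out.reshape(nx, ny, nz, *extra, order="F")


def _from_grid(vol: np.ndarray, n_voxels: int) -> np.ndarray:
    flat = vol.reshape(-1, *vol.shape[3:], order="F")
    return flat[:n_voxels]


def write_fixture(subject: SubjectData, out_dir: str | Path) -> dict[str, Path]:
    """Write a subject to disk: one 4-D NIfTI + events TSV per run, a 3-D
    integer layer-map NIfTI ({1 deep, 2 middle, 3 superficial}, 0 padding)
    and the ground-truth JSON. Round-trips through :func:`read_fixture`
    bit-exactly for integer maps and within float64 precision for data."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_vox = subject.runs[0].n_voxels
    paths: dict[str, Path] = {}
    affine = np.eye(4)
    for i, (ts, ev) in enumerate(zip(subject.runs, subject.events)):
        img = nib.Nifti1Image(_to_grid(ts.data, n_vox), affine)
        img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_s))
        p = out / f"run-{i:02d}_bold.nii"
        nib.save(img, p)
        paths[f"bold_{i}"] = p
        tsv = pd.DataFrame(
            {
                "onset": ev["onset_s"],
                "duration": ev["duration_s"],
                "trial_type": ev["condition"],
                "prev_trial_type": ev["prev_condition"].map(
                    lambda v: "n/a" if v is None or pd.isna(v) else v
                ),
            }
        )
        pe = out / f"run-{i:02d}_events.tsv"
        tsv.to_csv(pe, sep="\t", index=False)
        paths[f"events_{i}"] = pe
    codes = subject.layer_map["bin"].map(LAYER_CODES).to_numpy(dtype=np.int16)
    layer_img = nib.Nifti1Image(_to_grid(codes, n_vox)[..., ], affine)
    pl = out / "layers.nii"
    nib.save(layer_img, pl)
    paths["layers"] = pl
    pt = out / "ground_truth.json"
    pt.write_text(json.dumps(subject.truth, indent=1))
    paths["truth"] = pt
    return paths


def read_fixture(fix_dir: str | Path, tr_s: float | None = None) -> SubjectData:
    """Read a fixture written by :func:`write_fixture` (or any externally
    supplied data laid out the same way)."""
    import nibabel as nib

    fix = Path(fix_dir)
    layer_img = nib.load(fix / "layers.nii")
    layer_grid = np.asarray(layer_img.dataobj)
    flat = layer_grid.reshape(-1, order="F")
    n_vox = int(np.count_nonzero(flat))
    codes = flat[:n_vox].astype(int)
    inv = {v: k for k, v in LAYER_CODES.items()}
    layer_map = pd.DataFrame(
        {
            "voxel_id": [f"v{i:05d}" for i in range(n_vox)],
            "depth": np.nan,
            "bin": [inv[c] for c in codes],
            "analyzed": [inv[c] != "middle" for c in codes],
            "roi": "roi",
        }
    ).set_index("voxel_id")
    events, runs = [], []
    for i, p in enumerate(sorted(fix.glob("run-*_bold.nii"))):
        img = nib.load(p)
        tr = float(tr_s if tr_s is not None else img.header.get_zooms()[3])
        data = _from_grid(np.asarray(img.dataobj, dtype=np.float64), n_vox)
        runs.append(VoxelTimeSeries(data=data, tr_s=tr, run=i))
        tsv = pd.read_csv(fix / f"run-{i:02d}_events.tsv", sep="\t")
        events.append(
            pd.DataFrame(
                {
                    "onset_s": tsv["onset"],
                    "duration_s": tsv["duration"],
                    "condition": tsv["trial_type"],
                    "run": i,
                    "run_type": "load"
                    if set(tsv["trial_type"]) <= {"high", "low"}
                    else "motor",
                    "trial_index": np.arange(len(tsv)),
                    "prev_condition": tsv["prev_trial_type"].map(
                        lambda v: None if v == "n/a" or pd.isna(v) else v
                    ),
                }
            )
        )
    truth_path = fix / "ground_truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    spec = DesignSpec()
    return SubjectData(
        subject=str(truth.get("subject", "S01")), spec=spec, events=events,
        runs=runs, layer_map=layer_map, truth=truth,
    )
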
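"""FIR estimation of condition-specific trial timecourses.

Each condition's response is deconvolved with a *tent* (piecewise-linear)
basis whose first and last knots are constrained to zero: 17 knots over a
32 s window at TR = 2 s leave 15 free regressors at 2, 4, ..., 30 s. The
zero endpoints remove pre-stimulus offsets between trial types. Slow trends
are absorbed by per-run orthogonal polynomial nuisance regressors (up to
fifth order by default); the constant nuisance term doubles as the baseline
for percent-signal-change scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import VoxelTimeSeries
from .exceptions import RankError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class BasisMatrix:
    """Scans × regressors design block."""

    matrix: np.ndarray
    knot_times: np.ndarray | None
    kind: str  # "tentzero" | "nuisance"
    names: list[str] = field(default_factory=list)


@dataclass
class FIREstimates:
    """Per-condition tent coefficients (voxels × free knots).

    ``constant`` holds the run-mean baseline per voxel (the constant
    nuisance predictor); ``scale`` is "raw" or "psc"; ``valid`` flags voxels
    with a usable baseline after PSC conversion.
    """

    betas: dict[str, np.ndarray]
    constant: np.ndarray
    knot_times: np.ndarray
    scale: str
    voxel_ids: np.ndarray
    valid: np.ndarray
    window_s: float = 32.0
    n_knots: int = 17


@dataclass
class TrialTimecourse:
    """Layer- and condition-wise mean PSC timecourse on the free-knot grid."""

    values: dict[tuple[str, str], np.ndarray]
    knot_times: np.ndarray
    subject: str | None = None

    def full_curve(self, layer: str, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Timecourse including the zero-constrained endpoint knots."""
        dt = self.knot_times[1] - self.knot_times[0]
        times = np.concatenate(
            [[self.knot_times[0] - dt], self.knot_times, [self.knot_times[-1] + dt]]
        )
        curve = np.concatenate([[0.0], self.values[(layer, condition)], [0.0]])
        return times, curve


def build_tentzero_basis(
    onsets: np.ndarray,
    n_scans: int,
    tr_s: float,
    window_s: float = 32.0,
    n_knots: int = 17,
) -> BasisMatrix:
    """Tent basis with zero endpoints, evaluated at scan times.

    Knots sit at ``j * window_s/(n_knots-1)`` for j = 0..n_knots-1; the
    first and last carry no regressor. Free knot j contributes the tent
    ``max(0, 1 - |t - onset - k_j| / spacing)`` summed over event onsets.
    Onsets need not be TR-locked: off-grid events load fractionally onto
    neighbouring knots.
    """
    if n_knots < 3:
        raise ValidationError("n_knots must be >= 3")
    if window_s <= 0:
        raise ValidationError("window_s must be positive")
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    spacing = window_s / (n_knots - 1)
    free_knots = np.arange(1, n_knots - 1) * spacing
    t = np.arange(n_scans) * tr_s
    # scans x events lags
    lag = t[:, None] - onsets[None, :]
    cols = np.empty((n_scans, free_knots.size))
    for j, k in enumerate(free_knots):
        cols[:, j] = np.clip(1.0 - np.abs(lag - k) / spacing, 0.0, None).sum(axis=1)
    names = [f"tent@{k:g}s" for k in free_knots]
    return BasisMatrix(matrix=cols, knot_times=free_knots, kind="tentzero", names=names)


def build_nuisance(n_scans: int, order: int = 5) -> BasisMatrix:
    """Polynomial detrending block: degree 0..order, orthogonalized on the
    scan grid (QR of the Legendre Vandermonde). The constant column is kept
    as exact ones so its coefficient is the run baseline; higher columns are
    pairwise orthogonal to machine precision and scaled to unit max-abs."""
    if order < 0:
        raise ValidationError("order must be >= 0")
    if order >= n_scans:
        raise ValidationError(f"order={order} >= n_scans={n_scans}")
    x = np.linspace(-1.0, 1.0, n_scans) if n_scans > 1 else np.zeros(1)
    V = np.polynomial.legendre.legvander(x, order)
    Q, _ = np.linalg.qr(V)
    B = np.empty_like(Q)
    B[:, 0] = 1.0
    for k in range(1, order + 1):
        col = Q[:, k] / np.max(np.abs(Q[:, k]))
        if col[-1] < 0:  # Legendre convention: positive at the right edge
            col = -col
        B[:, k] = col
    names = [f"poly{k}" for k in range(order + 1)]
    return BasisMatrix(matrix=B[:, : order + 1], knot_times=None, kind="nuisance", names=names)


def fit_fir(
    runs: list[VoxelTimeSeries],
    events: list[pd.DataFrame],
    conditions: list[str] | None = None,
    window_s: float = 32.0,
    n_knots: int = 17,
    nuisance_order: int = 5,
) -> FIREstimates:
    """Ordinary-least-squares FIR fit on concatenated runs.

    The design holds one tent-basis block per condition (events pooled
    across runs, rows per run) and a block-diagonal per-run nuisance block.
    Returns raw-scale tent coefficients per condition and the run-mean
    constant predictor per voxel.
    """
    if len(runs) != len(events):
        raise ValidationError("runs and events must align")
    if not runs:
        raise ValidationError("need at least one run")
    tr = runs[0].tr_s
    n_vox = runs[0].n_voxels
    for r in runs:
        if r.tr_s != tr or r.n_voxels != n_vox:
            raise ValidationError("all runs must share TR and voxel set")
    if conditions is None:
        conditions = sorted(set().union(*(set(ev["condition"]) for ev in events)))
    for c in conditions:
        if not any((ev["condition"] == c).any() for ev in events):
            raise ValidationError(f"condition {c!r} has no events")

    cond_blocks, names = [], []
    knot_times = None
    for c in conditions:
        rows = []
        for r, ev in zip(runs, events):
            onsets = ev.loc[ev["condition"] == c, "onset_s"].to_numpy()
            if onsets.size:
                b = build_tentzero_basis(onsets, r.n_scans, tr, window_s, n_knots)
                knot_times = b.knot_times
                rows.append(b.matrix)
            else:
                rows.append(np.zeros((r.n_scans, n_knots - 2)))
        cond_blocks.append(np.vstack(rows))
        names += [f"{c}@{k:g}s" for k in knot_times]

    total_scans = sum(r.n_scans for r in runs)
    n_cond_cols = sum(b.shape[1] for b in cond_blocks)
    nuis_cols = []
    offset = 0
    const_cols = []
    for i, r in enumerate(runs):
        nb = build_nuisance(r.n_scans, nuisance_order)
        block = np.zeros((total_scans, nb.matrix.shape[1]))
        block[offset : offset + r.n_scans] = nb.matrix
        const_cols.append(n_cond_cols + sum(b.shape[1] for b in nuis_cols))
        nuis_cols.append(block)
        names += [f"run{i}_{n}" for n in nb.names]
        offset += r.n_scans

    X = np.hstack(cond_blocks + nuis_cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased regressors via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        aliased = [names[j] for j in piv[np.abs(np.diag(R)) < tol]]
        raise RankError(f"rank-deficient design; aliased regressors: {aliased}")

    Y = np.hstack([r.data for r in runs]).T  # total_scans x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    n_free = n_knots - 2
    betas = {
        c: beta[i * n_free : (i + 1) * n_free].T.copy() for i, c in enumerate(conditions)
    }
    constant = beta[const_cols].mean(axis=0)
    return FIREstimates(
        betas=betas,
        constant=constant,
        knot_times=knot_times,
        scale="raw",
        voxel_ids=runs[0].voxel_ids,
        valid=np.ones(n_vox, dtype=bool),
        window_s=window_s,
        n_knots=n_knots,
    )


def to_percent_signal_change(est: FIREstimates) -> FIREstimates:
    """Scale tent coefficients to percent signal change:
    ``100 * beta / constant`` per voxel. Voxels with a non-positive baseline
    are excluded (flagged invalid, coefficients set to NaN, logged)."""
    if est.scale != "raw":
        raise ValidationError("estimates are already on the PSC scale")
    valid = est.constant > 0
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("excluding %d voxel(s) with non-positive baseline from PSC", n_bad)
    denom = np.where(valid, est.constant, np.nan)
    betas = {c: 100.0 * b / denom[:, None] for c, b in est.betas.items()}
    return replace(est, betas=betas, scale="psc", valid=valid & est.valid)


def layer_timecourse(
    est: FIREstimates,
    layer_map: pd.DataFrame,
    roi: str | None = None,
    layers: tuple[str, ...] = ("superficial", "deep"),
    subject: str | None = None,
) -> TrialTimecourse:
    """Unweighted mean timecourse across a layer's (valid) ROI voxels,
    per condition and knot."""
    values: dict[tuple[str, str], np.ndarray] = {}
    for layer in layers:
        mask = (layer_map["bin"] == layer).to_numpy()
        if roi is not None:
            mask &= (layer_map["roi"] == roi).to_numpy()
        mask &= est.valid
        if not mask.any():
            raise ValidationError(f"no valid voxels for layer {layer!r} in ROI {roi!r}")
        for cond, b in est.betas.items():
            values[(layer, cond)] = b[mask].mean(axis=0)
    return TrialTimecourse(values=values, knot_times=est.knot_times, subject=subject)
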
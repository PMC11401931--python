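"""Layer-wise univariate effects over hemodynamically shifted trial periods.

The analysis windows already include the ~6 s hemodynamic delay: the delay
window is 11.3-15.1 s and the retrieval window 20.7-24.5 s post stimulus
onset. On a 2 s tent-knot grid those closed intervals capture the knots
{12, 14} and {22, 24} s respectively. Effects are condition contrasts of
the layer timecourses, averaged over the window knots, and compared across
layers with classical paired t-tests; Cohen's d for the paired design is
``t / sqrt(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .fir import TrialTimecourse


@dataclass(frozen=True)
class Period:
    """Closed analysis window in seconds post-onset (hemodynamically shifted)."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError("period start must be < end")


DELAY = Period("delay", 11.3, 15.1)
RETRIEVAL = Period("retrieval", 20.7, 24.5)

#: decoding-time task periods used for the period x layer interaction test
DECODING_PERIODS = {
    "encoding": (8.0, 12.0),
    "delay": (14.0, 20.0),
    "retrieval": (22.0, 24.0),
}


@dataclass
class EffectTimecourse:
    """Per-layer contrast (condition a − condition b) on the knot grid."""

    values: dict[str, np.ndarray]
    knot_times: np.ndarray
    contrast: tuple[str, str]
    subject: str | None = None


@dataclass
class TestResult:
    """Two-tailed paired t-test summary: t, df = n−1, p, 95% CI of the mean
    difference (units of the measure) and paired Cohen's d = t/sqrt(n)."""

    t: float
    df: int
    p: float
    ci95: tuple[float, float]
    d: float
    degenerate: bool = False


def condition_contrast(tc: TrialTimecourse, a: str, b: str) -> EffectTimecourse:
    """Pointwise a − b effect timecourse per layer."""
    layers = sorted({layer for layer, _ in tc.values})
    values = {}
    for layer in layers:
        if (layer, a) not in tc.values or (layer, b) not in tc.values:
            raise ValidationError(f"conditions {a!r}/{b!r} missing for layer {layer!r}")
        va, vb = tc.values[(layer, a)], tc.values[(layer, b)]
        if va.shape != vb.shape:
            raise ValidationError("mismatched knot grids between conditions")
        values[layer] = va - vb
    return EffectTimecourse(
        values=values, knot_times=tc.knot_times, contrast=(a, b), subject=tc.subject
    )


def period_average(effect: EffectTimecourse, period: Period) -> dict[str, float]:
    """Unweighted mean of the knots falling inside the closed window
    ``[start_s, end_s]``, per layer."""
    inside = (effect.knot_times >= period.start_s) & (effect.knot_times <= period.end_s)
    if not inside.any():
        raise ValidationError(f"no knots inside period {period.label!r}")
    return {layer: float(v[inside].mean()) for layer, v in effect.values.items()}


def paired_ttest(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Classical two-tailed paired t-test on x − y.

    Returns t, df, p, the 95% CI of the mean difference
    (mean ± t_{0.975,df}·SE) and paired Cohen's d = mean(diff)/sd(diff).
    Zero-variance differences with nonzero mean are flagged degenerate
    (p → 0, infinite d).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("x and y must be equal-length 1-D arrays with n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    diff = x - y
    n = diff.size
    df = n - 1
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(t=0.0, df=df, p=1.0, ci95=(0.0, 0.0), d=0.0)
        sign = float(np.sign(mean))
        return TestResult(
            t=sign * np.inf, df=df, p=0.0, ci95=(mean, mean), d=sign * np.inf,
            degenerate=True,
        )
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return TestResult(
        t=float(t),
        df=df,
        p=float(p),
        ci95=(float(mean - tcrit * se), float(mean + tcrit * se)),
        d=float(mean / sd),
    )


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size from the t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValidationError("n must be >= 2")
    return float(t / np.sqrt(n))
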
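"""Trial/run structure of the delayed match-to-sample working-memory task.

A session has *load* runs (high vs. low working-memory load) and *motor*
runs (respond vs. abstain at retrieval). Every trial follows a fixed clock:
sample (3.5 s) + visual mask (0.2 s), delay (13 s), probe/response window
(4.2 s), inter-trial interval (10 s) — 30.7 s in total. A run holds 16
trials and lasts 8 min 24 s; the remainder of the run (12.8 s by default)
is a lead-in before the first trial. Trial onsets are therefore *not*
locked to the 2 s TR grid.

Condition sequences are counterbalanced (equal trial counts per condition)
and pseudorandomized with a bounded streak: at most ``max_consecutive_same``
trials of the same type in a row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConstraintError, ValidationError

#: condition labels by run type
LOAD_CONDITIONS = ("high", "low")
MOTOR_CONDITIONS = ("response", "abstain")

#: canonical trial periods (task clock, seconds post-onset, half-open)
PERIOD_NAMES = ("encoding", "delay", "retrieval")

#: duration of the post-sample visual mask, part of the encoding period
MASK_S = 0.2


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the session design.

    Defaults encode the study conditions: 2 load + 2 motor runs of 16
    trials, 30.7 s trials, TR = 2 s, streaks capped at 3.
    """

    n_runs_load: int = 2
    n_runs_motor: int = 2
    trials_per_run: int = 16
    trial_duration_s: float = 30.7
    sample_s: float = 3.5
    delay_s: float = 13.0
    response_window_s: float = 4.2
    iti_s: float = 10.0
    max_consecutive_same: int = 3
    tr_s: float = 2.0
    lead_in_s: float = 12.8

    def __post_init__(self) -> None:
        total = self.sample_s + self.delay_s + self.response_window_s + self.iti_s
        if abs(total - self.trial_duration_s) > 1e-9:
            raise ValidationError(
                f"component durations sum to {total} s, expected trial_duration_s="
                f"{self.trial_duration_s} s"
            )
        if self.trials_per_run % 2 != 0:
            raise ValidationError("trials_per_run must be even (two conditions)")
        if self.max_consecutive_same < 1:
            raise ValidationError("max_consecutive_same must be >= 1")
        if self.tr_s <= 0 or self.trial_duration_s <= 0:
            raise ValidationError("tr_s and trial_duration_s must be positive")
        if self.lead_in_s < 0:
            raise ValidationError("lead_in_s must be >= 0")

    @property
    def run_duration_s(self) -> float:
        return self.lead_in_s + self.trials_per_run * self.trial_duration_s

    @property
    def n_scans(self) -> int:
        return int(math.ceil(self.run_duration_s / self.tr_s))

    @property
    def n_runs(self) -> int:
        return self.n_runs_load + self.n_runs_motor

    def period_windows(self) -> dict[str, tuple[float, float]]:
        """Task-clock signal-injection windows (seconds post onset).

        Encoding covers sample + mask; the windows tile the active part of
        the trial and end before the inter-trial interval.
        """
        e_end = self.sample_s + MASK_S
        d_end = e_end + self.delay_s
        r_end = d_end + self.response_window_s
        return {
            "encoding": (0.0, e_end),
            "delay": (e_end, d_end),
            "retrieval": (d_end, r_end),
        }


def _sequence_feasible(rem_same: int, rem_other: int, streak: int, max_streak: int) -> bool:
    """Can `rem_same` of the current symbol and `rem_other` of the other be
    arranged after a trailing streak of length `streak`, with runs <= max_streak?

    Two-symbol criterion: the current symbol's first block may hold at most
    ``max_streak - streak`` items, subsequent blocks at most ``max_streak``,
    with ``rem_other`` separators available; and symmetrically for the other
    symbol (whose first block is unconstrained by the trailing streak).
    """
    if rem_same < 0 or rem_other < 0:
        return False
    # blocks of the current symbol: 1 + rem_other possible slots
    if rem_same > (max_streak - streak) + rem_other * max_streak:
        return False
    if rem_other > (rem_same + 1) * max_streak:
        return False
    return True


def _pseudorandom_sequence(
    conditions: tuple[str, str], n: int, max_streak: int, rng: np.random.Generator
) -> list[str]:
    """Counterbalanced two-condition sequence with bounded streaks.

    Sequential construction: at each position, draw uniformly among the
    conditions that still have trials left, do not extend a streak past the
    bound, and leave a feasible completion. Raises if no feasible start
    exists (e.g. a bound that cannot host equal counts).
    """
    counts = {c: n // 2 for c in conditions}
    seq: list[str] = []
    last, streak = None, 0
    for _ in range(n):
        candidates = []
        for c in conditions:
            if counts[c] == 0:
                continue
            new_streak = streak + 1 if c == last else 1
            if new_streak > max_streak:
                continue
            other = conditions[1] if c == conditions[0] else conditions[0]
            if _sequence_feasible(counts[c] - 1, counts[other], new_streak, max_streak):
                candidates.append(c)
        if not candidates:
            raise ConstraintError(
                f"cannot satisfy max_consecutive_same={max_streak} with "
                f"{n} counterbalanced trials"
            )
        c = candidates[int(rng.integers(len(candidates)))]
        seq.append(c)
        counts[c] -= 1
        streak = streak + 1 if c == last else 1
        last = c
    return seq


EVENT_COLUMNS = [
    "onset_s",
    "duration_s",
    "condition",
    "run",
    "run_type",
    "trial_index",
    "prev_condition",
]


def generate_design(spec: DesignSpec, seed: int) -> list[pd.DataFrame]:
    """Generate one event table per run (load runs first, then motor runs).

    Each table has columns ``onset_s, duration_s, condition, run, run_type,
    trial_index, prev_condition``. Onsets follow the fixed trial clock
    (``lead_in_s + k * trial_duration_s``), which is not TR-locked when the
    trial duration is not a TR multiple. ``prev_condition`` of trial k is
    the condition of trial k−1; the first trial of a run inherits the last
    trial of the preceding run *of the same run type* (None if there is
    none).
    """
    rng = np.random.default_rng(seed)
    run_plan = [("load", LOAD_CONDITIONS)] * spec.n_runs_load + [
        ("motor", MOTOR_CONDITIONS)
    ] * spec.n_runs_motor
    tables: list[pd.DataFrame] = []
    last_by_type: dict[str, str] = {}
    for run_idx, (run_type, conditions) in enumerate(run_plan):
        seq = _pseudorandom_sequence(
            conditions, spec.trials_per_run, spec.max_consecutive_same, rng
        )
        onsets = spec.lead_in_s + np.arange(spec.trials_per_run) * spec.trial_duration_s
        prev = [last_by_type.get(run_type)] + seq[:-1]
        df = pd.DataFrame(
            {
                "onset_s": onsets,
                "duration_s": spec.trial_duration_s,
                "condition": seq,
                "run": run_idx,
                "run_type": run_type,
                "trial_index": np.arange(spec.trials_per_run),
                "prev_condition": prev,
            }
        )
        last_by_type[run_type] = seq[-1]
        tables.append(df)
    return tables


def simulate_behavior(
    events: pd.DataFrame,
    acc_by_condition: dict[str, float],
    rt_by_condition: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli behavioural outcomes per trial.

    ``acc_by_condition`` maps each condition present in ``events`` to its
    probability of a correct trial. Abstain trials are "correct" when the
    participant withholds the response; their reaction time is None.
    Response times (when given) are drawn from a shifted lognormal around
    the condition's mean RT.
    """
    rng = np.random.default_rng(seed)
    rt_by_condition = rt_by_condition or {}
    rows = []
    for _, tr in events.iterrows():
        cond = tr["condition"]
        if cond not in acc_by_condition:
            raise ValidationError(f"missing accuracy rate for condition {cond!r}")
        acc = acc_by_condition[cond]
        if not 0.0 <= acc <= 1.0:
            raise ValidationError(f"accuracy for {cond!r} outside [0, 1]")
        correct = bool(rng.random() < acc)
        if cond == "abstain":
            rt = None
        else:
            mean_rt = rt_by_condition.get(cond, 1.2)
            rt = float(0.2 + rng.lognormal(mean=np.log(max(mean_rt - 0.2, 1e-3)), sigma=0.25))
        rows.append(
            {
                "run": tr["run"],
                "trial_index": tr["trial_index"],
                "condition": cond,
                "correct": correct,
                "rt_s": rt,
            }
        )
    return pd.DataFrame(rows)
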
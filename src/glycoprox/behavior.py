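"""T-maze olfactory behavior statistics.

Two kinds of trial are quantified. Odor acuity: ~100 naive flies choose
between air and an aversive odor (4-methylcyclohexanol, MCH, or 3-octanol,
OCT) for 2 minutes;

    PI_odor = [n(Air) − n(odor)] / [n(Air) + n(odor)] × 100%.

Associative learning: flies are trained to pair one odor (CS+) with electric
shock, then choose between the two odors;

    PI = [n(CS−) − n(CS+)] / [n(CS−) + n(CS+)] × 100%.

Each reported learning score is the mean of two reciprocal trials — one with
MCH shock-paired, one with OCT — which cancels any innate odor bias; a
reciprocal pair involves approximately 200 flies. Group comparisons use the
shared unpaired Student's t-test kernel.

PI values are carried as exact integer ratios (``fractions.Fraction``) and
rendered at a fixed precision, so reciprocal means reproduce bit-for-bit in
output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .stats import TTestResult, two_sample_t

__all__ = [
    "BehaviorTrial",
    "PerformanceIndex",
    "odor_pi",
    "learning_pi",
    "reciprocal_mean",
    "compare_groups",
    "read_trials",
    "pi_table",
]

ODORS = ("MCH", "OCT")
PI_DECIMALS = 4  # fixed rendering precision of PI values in output files


@dataclass(frozen=True)
class BehaviorTrial:
    """One T-maze trial's fly counts.

    For ``kind="acuity"`` set ``n_air``/``n_odor`` (flies choosing the air arm
    vs the odor arm); for ``kind="learning"`` set ``n_cs_minus``/``n_cs_plus``
    (flies avoiding vs choosing the shock-paired odor).
    """

    kind: str
    odor: str
    group: str = ""
    n_air: int | None = None
    n_odor: int | None = None
    n_cs_minus: int | None = None
    n_cs_plus: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("acuity", "learning"):
            raise ValueError(f"kind must be 'acuity' or 'learning', got {self.kind!r}")
        if self.odor not in ODORS:
            raise ValueError(f"odor must be one of {ODORS}, got {self.odor!r}")
        counts = (
            (self.n_air, self.n_odor) if self.kind == "acuity" else (self.n_cs_minus, self.n_cs_plus)
        )
        if any(c is None for c in counts):
            raise ValueError(f"{self.kind} trial needs both arm counts")
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError("fly counts must be non-negative integers")
        if sum(counts) < 1:
            raise ValueError("trial has zero flies")


@dataclass(frozen=True)
class PerformanceIndex:
    """A performance index in percent, exact as a ratio of integer counts."""

    value: Fraction
    n_total: int
    odor: str | None = None

    def __post_init__(self) -> None:
        if not -100 <= self.value <= 100:
            raise ValueError(f"PI out of bounds: {self.value}")

    def __float__(self) -> float:
        return float(self.value)

    def render(self) -> str:
        return f"{float(self.value):.{PI_DECIMALS}f}"


def _pi(n_pos: int, n_neg: int, odor: str) -> PerformanceIndex:
    total = n_pos + n_neg
    if total < 1:
        raise ValueError("cannot compute a PI with zero flies")
    return PerformanceIndex(Fraction(100 * (n_pos - n_neg), total), total, odor)


def odor_pi(trial: BehaviorTrial) -> PerformanceIndex:
    """Odor-acuity PI: positive when flies avoid the aversive odor."""
    if trial.kind != "acuity":
        raise ValueError("odor_pi expects an acuity trial")
    return _pi(trial.n_air, trial.n_odor, trial.odor)


def learning_pi(trial: BehaviorTrial) -> PerformanceIndex:
    """Learning PI: positive when flies avoid the shock-paired odor."""
    if trial.kind != "learning":
        raise ValueError("learning_pi expects a learning trial")
    return _pi(trial.n_cs_minus, trial.n_cs_plus, trial.odor)


def reciprocal_mean(pi_mch: PerformanceIndex, pi_oct: PerformanceIndex) -> PerformanceIndex:
    """Mean PI of a reciprocal odor pair (cancels innate odor preference)."""
    if pi_mch.odor == pi_oct.odor:
        raise ValueError("reciprocal pair must use the two different shock-paired odors")
    return PerformanceIndex(
        (pi_mch.value + pi_oct.value) / 2, pi_mch.n_total + pi_oct.n_total, None
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided unpaired Student's t-test between two groups of PI values."""
    return two_sample_t([float(v) for v in a], [float(v) for v in b])


def read_trials(path) -> list[BehaviorTrial]:
    """Read a trial CSV with columns group, kind, odor, count1, count2.

    count1/count2 are n_air/n_odor for acuity trials and n_cs_minus/n_cs_plus
    for learning trials.
    """
    df = pd.read_csv(path)
    for col in ("group", "kind", "odor", "count1", "count2"):
        if col not in df.columns:
            raise ValueError(f"trial table missing column {col!r}")
    trials = []
    for r in df.itertuples(index=False):
        if r.kind == "acuity":
            trials.append(
                BehaviorTrial("acuity", r.odor, str(r.group), n_air=int(r.count1), n_odor=int(r.count2))
            )
        else:
            trials.append(
                BehaviorTrial(
                    "learning", r.odor, str(r.group), n_cs_minus=int(r.count1), n_cs_plus=int(r.count2)
                )
            )
    return trials


def pi_table(trials: Sequence[BehaviorTrial]) -> pd.DataFrame:
    """Per-trial PI table (group, kind, odor, n_total, pi)."""
    rows = []
    for t in trials:
        pi = odor_pi(t) if t.kind == "acuity" else learning_pi(t)
        rows.append((t.group, t.kind, t.odor, pi.n_total, float(pi.value)))
    return pd.DataFrame(rows, columns=["group", "kind", "odor", "n_total", "pi"])
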
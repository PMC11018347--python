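"""Shared two-sample t-test kernel.

A single equal-variance (Student's) two-sample t-test implementation is used
everywhere a group comparison is needed: for per-protein CD-vs-DM differential
enrichment on log2-transformed LFQ intensities, and for comparing T-maze
performance indices between genotypes.

Degenerate-variance inputs are resolved by their limit behaviour instead of
propagating NaN: if both groups are constant with equal means the groups are
indistinguishable (t = 0, p = 1); if both are constant with different means the
separation is perfect (t = +/-inf, p = 0). Such results carry a ``degenerate``
flag so downstream consumers can report them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["TTestResult", "two_sample_t"]


@dataclass(frozen=True)
class TTestResult:
    """Result of an equal-variance two-sample t-test.

    Attributes
    ----------
    statistic:
        Student's t statistic (x̄ − ȳ scaled by the pooled standard error).
        ``+inf``/``-inf`` in the degenerate constant-but-unequal case.
    p_value:
        Two-sided p-value from the t distribution with ``df`` degrees of
        freedom.
    df:
        Degrees of freedom, n_x + n_y − 2.
    degenerate:
        True when the pooled variance was zero and the limit convention was
        applied.
    """

    statistic: float
    p_value: float
    df: int
    degenerate: bool = False


def two_sample_t(x, y) -> TTestResult:
    """Two-sided unpaired Student's (equal-variance) t-test.

    Parameters
    ----------
    x, y:
        1-D sequences of measurements, at least two per group.

    Returns
    -------
    TTestResult

    Notes
    -----
    t = (x̄ − ȳ) / (s_p · sqrt(1/n_x + 1/n_y)) with the pooled variance
    s_p² = [(n_x − 1)s_x² + (n_y − 1)s_y²] / (n_x + n_y − 2); the p-value is
    2·P(T_df ≥ |t|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("two_sample_t expects 1-D samples")
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError(
            f"two_sample_t requires at least 2 observations per group, got {nx} and {ny}"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("two_sample_t requires finite inputs")

    df = nx + ny - 2
    diff = x.mean() - y.mean()
    ssx = ((x - x.mean()) ** 2).sum()
    ssy = ((y - y.mean()) ** 2).sum()
    pooled_var = (ssx + ssy) / df

    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 1.0, df, degenerate=True)
        return TTestResult(math.copysign(math.inf, diff), 0.0, df, degenerate=True)

    se = math.sqrt(pooled_var * (1.0 / nx + 1.0 / ny))
    t = diff / se
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TTestResult(float(t), min(p, 1.0), df)
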
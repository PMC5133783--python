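"""Student t-tests and multiple-testing helpers shared across the pipeline.

The imaging comparisons use a two-tailed unpaired Student t-test (pooled
variance); the clonogenic comparisons use a one-tailed paired t-test.  The t
statistic is computed here explicitly so that degenerate zero-variance inputs
(e.g. two identical samples) behave predictably; p-values come from scipy's
t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class StatTestResult:
    name: str
    tails: int
    paired: bool
    statistic: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")


def _p_from_t(t: float, df: float, tails: int, alternative: str) -> float:
    if tails == 2:
        return float(2.0 * sps.t.sf(abs(t), df))
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    return float(sps.t.cdf(t, df))


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    tails: int = 2,
    paired: bool = False,
    alternative: str = "two-sided",
    welch: bool = False,
) -> StatTestResult:
    """Student's t-test between two samples.

    Parameters
    ----------
    tails
        2 for a two-sided test; 1 requires ``alternative`` to name a
        direction ("greater" tests mean(x) > mean(y)).
    paired
        Paired test on elementwise differences (equal lengths required).
    welch
        Unequal-variance (Welch) unpaired test instead of the classic
        pooled-variance Student test.

    Zero-variance inputs are handled explicitly: identical samples give
    t = 0 (two-sided p = 1); a nonzero mean difference with zero variance
    gives t = ±inf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if tails == 1 and alternative not in ("greater", "less"):
        raise ValueError("one-tailed test requires alternative='greater' or 'less'")
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test requires equal-length samples")
        if x.size < 2:
            raise ValueError("paired test requires >= 2 pairs")
        d = x - y
        n = d.size
        m = d.mean()
        sd = d.std(ddof=1)
        df = float(n - 1)
        if sd == 0.0:
            t = 0.0 if m == 0.0 else math.copysign(math.inf, m)
        else:
            t = m / (sd / math.sqrt(n))
        name = "paired t"
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("unpaired test requires >= 2 observations per sample")
        nx, ny = x.size, y.size
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        diff = x.mean() - y.mean()
        if welch:
            se2 = vx / nx + vy / ny
            if se2 == 0.0:
                df = float(nx + ny - 2)
                t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            else:
                df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
                t = diff / math.sqrt(se2)
            name = "Welch t"
        else:
            df = float(nx + ny - 2)
            sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
            if sp2 == 0.0:
                t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            else:
                t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
            name = "Student t"
    p = _p_from_t(t, df, tails, alternative)
    return StatTestResult(name=name, tails=tails, paired=paired,
                          statistic=float(t), df=df, p=p)


def holm(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
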
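"""Shared statistical kernels: SEM, correlation t-test, Pearson chi-square."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def sem(values) -> float:
    """Standard error of the mean: sample sd (ddof=1) / sqrt(n); NaN for n < 2."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t statistic and two-sided p-value.

    t = r * sqrt(n - 2) / sqrt(1 - r^2), compared with a t distribution on
    n - 2 degrees of freedom.
    """

    r: float
    n: int
    t: float
    p: float


def correlation_t_test(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must be paired")
    if n < 3:
        raise ValueError("correlation t-test requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), n, float("nan"), float("nan"))
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r, n, math.copysign(math.inf, r), 0.0)
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r, n, t, p)


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, df=1, no continuity
    correction; returns (chi2, two-sided p)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
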
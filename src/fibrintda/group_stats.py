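"""Paired group statistics for per-image metrics.

The experimental design is paired: each subject contributes a baseline and a
treated image, and per-image metrics (Wasserstein distance from the diagonal,
fractal dimension, feature counts) are compared with a classical two-sided
paired t-test at the 5% level, with t-based 95% confidence intervals.  No
multiple-testing correction is applied across metric families.

Sign convention: ``mean_difference = mean(treated) - mean(baseline)``, so an
intervention that reduces a metric yields a negative estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PairedComparison", "GroupSummary", "paired_t_test", "summarize_group"]

CONFIDENCE = 0.95


@dataclass
class PairedComparison:
    metric: str
    differences: np.ndarray
    mean_difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False  # zero-variance differences: t and p undefined


@dataclass
class GroupSummary:
    metric: str
    mean: float
    ci_low: float
    ci_high: float
    n: int


def paired_t_test(baseline, treated, metric: str = "") -> PairedComparison:
    """Two-sided paired t-test of treated vs baseline values.

    Returns the per-pair differences (treated - baseline), their mean, a
    t-based 95% CI, the t statistic and p value.  Zero-variance differences
    make the t statistic undefined; the result is flagged ``degenerate`` with
    ``p_value = nan`` (the CI collapses to the mean difference).
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(treated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("baseline and treated must be 1D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = y - x
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return PairedComparison(metric, diff, mean, mean, mean, np.nan, np.nan, n, True)
    se = sd / np.sqrt(n)
    tq = stats.t.ppf(0.5 + CONFIDENCE / 2.0, n - 1)
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    return PairedComparison(
        metric, diff, mean, mean - tq * se, mean + tq * se, float(t_stat), float(p), n
    )


def summarize_group(values, metric: str = "") -> GroupSummary:
    """Mean with t-based 95% CI; for fewer than 2 values the CI is undefined."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1D array")
    mean = float(v.mean())
    if v.size < 2:
        return GroupSummary(metric, mean, np.nan, np.nan, int(v.size))
    se = float(v.std(ddof=1)) / np.sqrt(v.size)
    tq = stats.t.ppf(0.5 + CONFIDENCE / 2.0, v.size - 1)
    return GroupSummary(metric, mean, mean - tq * se, mean + tq * se, int(v.size))
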
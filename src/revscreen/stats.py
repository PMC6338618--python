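"""Small statistical utilities used across the pipeline."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-test p-value.

    p uses t = r * sqrt((n-2)/(1-r^2)) against a t distribution with n-2
    degrees of freedom (scipy's exact formulation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length samples of n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson is undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def ttest_two_sided(a, b) -> tuple[float, float]:
    """Classical unpaired two-sample t-test (pooled variance), two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def mannwhitney_one_tailed(a, b, alternative: str = "greater") -> tuple[float, float]:
    """Mann-Whitney U, one-tailed, normal approximation with tie correction.

    ``alternative`` declares the hypothesized direction of sample ``a``
    relative to ``b`` ("greater" or "less"); a one-tailed test is
    meaningless without it.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs n >= 1")
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def percent_reduction(treated_mean: float, control_mean: float) -> float:
    """Percent reduction of a treated group mean relative to control."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (1.0 - treated_mean / control_mean)
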
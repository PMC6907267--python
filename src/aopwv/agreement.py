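"""Agreement and comparison statistics for paired PWV measurements.

Bland-Altman bias with 1.96-SD limits of agreement, two-way random-effects
absolute-agreement single-measure intraclass correlation (ICC(2,1)),
univariate linear regression, and the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BlandAltman",
    "bland_altman",
    "icc",
    "linreg",
    "ranksum",
]


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired measurements must be equal-length 1-D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values must be excluded upstream")
    return a, b


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    lower_la: float
    upper_la: float
    sd: float
    n: int


def bland_altman(a, b) -> BlandAltman:
    """Mean bias of a - b and limits of agreement bias +/- 1.96 sd.

    Sample standard deviation (n - 1 denominator).
    """
    a, b = _paired(a, b)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        lower_la=bias - 1.96 * sd,
        upper_la=bias + 1.96 * sd,
        sd=sd,
        n=int(d.size),
    )


def icc(a, b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Standard mean-squares decomposition for n subjects rated by k = 2
    methods:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    a, b = _paired(a, b)
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def linreg(x, y) -> dict:
    """Univariate OLS fit with Pearson R and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 (x, y) pairs of equal length")
    if np.ptp(x) == 0:
        raise ValueError("x has no spread; regression undefined")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
    }


def ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for small samples without ties; normal
    approximation with tie correction otherwise (no continuity
    correction, so identical groups give p = 1 exactly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both groups need at least 3 observations")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)
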
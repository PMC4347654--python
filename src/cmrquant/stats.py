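"""Accuracy and reproducibility statistics for method-comparison studies.

Single-measure two-way intraclass correlation for absolute agreement,
Bland-Altman limits of agreement, paired t-tests, Wilcoxon signed-rank
comparison of squared differences (the conventional test for comparing
reproducibilities), and Pearson correlation. All operate on paired arrays or
subjects x raters matrices in %LVM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsError",
    "icc",
    "icc_absolute_agreement",
    "icc_consistency",
    "icc_category",
    "BlandAltman",
    "bland_altman",
    "paired_t",
    "wilcoxon_squared_diffs",
    "pearson",
    "AgreementReport",
    "agreement_report",
    "plot_bland_altman",
]


class StatsError(ValueError):
    """Invalid input for an agreement statistic."""


def _as_matrix(ratings) -> np.ndarray:
    x = np.asarray(ratings, float)
    if x.ndim != 2:
        raise StatsError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise StatsError("need >= 2 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise StatsError("missing cells are not allowed (no imputation)")
    return x


def icc(ratings, absolute_agreement: bool = True) -> float:
    """Single-measure two-way intraclass correlation coefficient.

    With ``absolute_agreement=True`` (default) this is the absolute-agreement
    form ICC(A,1) = (MSr - MSe) / (MSr + (k-1) MSe + (k/n)(MSc - MSe)),
    which penalises systematic rater offsets; the consistency form
    ICC(C,1) = (MSr - MSe) / (MSr + (k-1) MSe) ignores them. Mean squares
    come from the two-way ANOVA decomposition with subjects as rows and
    raters (or methods) as columns.
    """
    x = _as_matrix(ratings)
    n, k = x.shape
    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    if sst == 0.0:
        raise StatsError("zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if absolute_agreement:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        denom = msr + (k - 1) * mse
    if denom == 0.0:
        raise StatsError("degenerate ANOVA decomposition; ICC undefined")
    return float((msr - mse) / denom)


def icc_absolute_agreement(ratings) -> float:
    return icc(ratings, absolute_agreement=True)


def icc_consistency(ratings) -> float:
    return icc(ratings, absolute_agreement=False)


def icc_category(value: float) -> str:
    """Conventional qualitative ICC bins.

    excellent (>= 0.75), good (0.60-0.74), fair (0.40-0.59), poor (< 0.40).
    """
    if not -1.0 <= value <= 1.0:
        raise StatsError("ICC must lie in [-1, 1]")
    if value >= 0.75:
        return "excellent"
    if value >= 0.60:
        return "good"
    if value >= 0.40:
        return "fair"
    return "poor"


class BlandAltman(NamedTuple):
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(a, b, multiplier: float = 1.96) -> BlandAltman:
    """Mean difference and limits of agreement: bias +/- 1.96 x SD(a - b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("a and b must be paired 1-D arrays")
    if a.size < 2:
        raise StatsError("need n >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    half_width = multiplier * float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - half_width, loa_high=bias + half_width)


def paired_t(a, b) -> float:
    """Two-sided paired t-test p-value, t = mean(d) / (SD(d)/sqrt(n)).

    A constant nonzero difference has zero variance and an infinite t
    statistic; the p-value is returned as the limit 0.0. Identical inputs
    (zero difference variance and zero mean) are an error.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise StatsError("need paired 1-D arrays with n >= 2")
    d = a - b
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if float(d.mean()) == 0.0:
            raise StatsError("zero difference variance; paired t undefined")
        return 0.0
    t = float(d.mean()) / (sd / np.sqrt(d.size))
    return float(2.0 * sps.t.sf(abs(t), df=d.size - 1))


def wilcoxon_squared_diffs(diffs_method1, diffs_method2) -> float:
    """Wilcoxon signed-rank comparison of squared paired differences.

    Each input holds one inter- (or intra-) observer difference per subject
    under one method; the test is run on d1^2 - d2^2 and asks whether one
    method's differences are systematically smaller (better reproducibility).
    Exact null distribution when n <= 25 and no zeros/ties; otherwise the
    normal approximation with Pratt zero handling.
    """
    d1 = np.asarray(diffs_method1, float)
    d2 = np.asarray(diffs_method2, float)
    if d1.shape != d2.shape or d1.ndim != 1 or d1.size < 2:
        raise StatsError("need paired 1-D arrays with n >= 2")
    x = d1 * d1 - d2 * d2
    if np.all(x == 0):
        raise StatsError("all squared differences tied; test undefined")
    has_zeros = bool(np.any(x == 0))
    nonzero = np.abs(x[x != 0])
    has_ties = len(np.unique(nonzero)) < len(nonzero)
    if x.size <= 25 and not has_zeros and not has_ties:
        res = sps.wilcoxon(x, method="exact")
    else:
        res = sps.wilcoxon(x, zero_method="pratt", method="approx", correction=True)
    return float(res.pvalue)


def pearson(a, b) -> tuple[float, float]:
    """Product-moment correlation and two-sided p (via the t transform)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise StatsError("need paired 1-D arrays with n >= 3")
    if a.std() == 0.0 or b.std() == 0.0:
        raise StatsError("constant input; correlation undefined")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


@dataclass
class AgreementReport:
    """One method-vs-reference (or rater-vs-rater) agreement summary."""

    icc: float
    icc_category: str
    bias: float
    loa_low: float
    loa_high: float
    paired_t_p: float | None
    n: int
    wilcoxon_p: float | None = None
    pearson_r: float | None = None


def agreement_report(a, b) -> AgreementReport:
    """Full agreement summary of paired measurements ``a`` vs reference ``b``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    icc_value = icc(np.column_stack([a, b]))
    ba = bland_altman(a, b)
    try:
        p = paired_t(a, b)
    except StatsError:
        p = None
    return AgreementReport(
        icc=icc_value,
        icc_category=icc_category(max(-1.0, min(1.0, icc_value))),
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        paired_t_p=p,
        n=int(a.size),
    )


def plot_bland_altman(a, b, ax=None, multiplier: float = 1.96):
    """Bland-Altman scatter with bias and limits of agreement drawn."""
    import matplotlib.pyplot as plt

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ba = bland_altman(a, b, multiplier=multiplier)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=18)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of pair (%LVM)")
    ax.set_ylabel("difference (%LVM)")
    return ax
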
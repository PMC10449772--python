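"""Agreement statistics for paired pullback measurements.

Covers landmark-based frame matching, paired location tests (paired t and
Wilcoxon signed-rank), Pearson correlation, the two-way random-effects
absolute-agreement single-measure intraclass correlation ICC(2,1) with its
F-based confidence interval, Bland-Altman limits of agreement, paired
t-test sample-size calculation by exact noncentral-t power, and the
contrast-induced-nephropathy (CIN) creatinine rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "MatchResult",
    "PairedTestResult",
    "ICCResult",
    "BlandAltmanResult",
    "AgreementReport",
    "match_pullbacks",
    "paired_compare",
    "correlation",
    "icc_agreement",
    "bland_altman",
    "paired_ttest_power",
    "paired_sample_size",
    "classify_cin",
    "agreement_report",
    "plot_bland_altman",
]


class LandmarkMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class MatchResult:
    """Frame offset between two pullbacks and the matched frame ranges.

    Frame ``i`` of pullback A corresponds to frame ``i + offset`` of B.
    """

    offset: int
    frames_a: range
    frames_b: range


def match_pullbacks(
    landmarks_a: Sequence[int],
    landmarks_b: Sequence[int],
    n_frames_a: int,
    n_frames_b: int,
    tolerance: int = 2,
) -> MatchResult:
    """Align two pullbacks by fiduciary landmark frames (side branches,
    stent edges).

    The offset is the median of the pairwise landmark index differences;
    any landmark deviating from it by more than ``tolerance`` frames makes
    the correspondence inconsistent.
    """
    la, lb = np.asarray(landmarks_a, int), np.asarray(landmarks_b, int)
    if la.size == 0 or la.size != lb.size:
        raise LandmarkMismatchError(
            f"landmark mismatch: {la.size} vs {lb.size} landmarks"
        )
    diffs = lb - la
    offset = int(round(float(np.median(diffs))))
    if np.any(np.abs(diffs - offset) > tolerance):
        raise LandmarkMismatchError(
            f"landmark mismatch: differences {diffs.tolist()} inconsistent with offset {offset}"
        )
    start_a = max(0, -offset)
    stop_a = min(n_frames_a, n_frames_b - offset)
    if stop_a <= start_a:
        raise LandmarkMismatchError("no overlapping frames after alignment")
    return MatchResult(
        offset=offset,
        frames_a=range(start_a, stop_a),
        frames_b=range(start_a + offset, stop_a + offset),
    )


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    t_statistic: float
    t_pvalue: float
    wilcoxon_pvalue: float
    n: int
    degenerate: bool = False  # all differences zero


def _check_pairs(a, b, min_n=2):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired arms must be 1-D and of equal length")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired values must be finite")
    return a, b


def paired_compare(a, b) -> PairedTestResult:
    """Paired t-test and Wilcoxon signed-rank test on matched measurements.

    Wilcoxon uses the zero-excluding convention for ties at zero. When all
    differences are zero both tests are degenerate; p = 1 is reported with
    the degenerate flag set.
    """
    a, b = _check_pairs(a, b)
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(0.0, 0.0, 1.0, 1.0, a.size, degenerate=True)
    t_stat, t_p = _st.ttest_rel(a, b)
    try:
        w_p = float(_st.wilcoxon(a, b, zero_method="wilcox").pvalue)
    except ValueError:
        w_p = 1.0
    return PairedTestResult(
        mean_difference=float(np.mean(d)),
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        wilcoxon_pvalue=w_p,
        n=a.size,
    )


def correlation(a, b) -> tuple[float, float]:
    """Pearson r and R^2 of the paired measurements."""
    a, b = _check_pairs(a, b, min_n=3)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one arm; correlation undefined")
    r = float(_st.pearsonr(a, b).statistic)
    return r, r * r


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int


def icc_agreement(a, b, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of the n x 2 table with
    subjects as rows and measurement methods as columns; the confidence
    interval is the standard F-based interval.
    """
    a, b = _check_pairs(a, b, min_n=3)
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("zero total variance; ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong) for ICC(A,1)
    if mse <= 0:
        lo, hi = icc, icc
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (
            n * (1 + (k - 1) * icc) - k * icc
        ) ** 2
        v = vn / vd
        f1 = _st.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = _st.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(
        icc=float(icc),
        ci_lower=float(lo),
        ci_upper=float(hi),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n=n,
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD)."""
    a, b = _check_pairs(a, b)
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd, sd_diff=sd
    )


def plot_bland_altman(a, b, ax=None, label_a="method A", label_b="method B"):
    """Bland-Altman scatter of difference against mean with bias/LoA lines."""
    import matplotlib.pyplot as plt

    a, b = _check_pairs(a, b)
    res = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=12, alpha=0.7)
    for yv, style in ((res.bias, "-"), (res.loa_lower, "--"), (res.loa_upper, "--")):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} - {label_b}")
    return ax


# ---------------------------------------------------------------------------
# power / sample size


def paired_ttest_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided paired t-test at standardized effect d.

    The test statistic on n paired differences follows a noncentral t
    distribution with n-1 degrees of freedom and noncentrality d*sqrt(n).
    """
    if n < 2:
        return 0.0
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = _st.t.ppf(1 - alpha / 2, df)
    return float(_st.nct.sf(tcrit, df, nc) + _st.nct.cdf(-tcrit, df, nc))


def paired_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.9, n_max: int = 1_000_000
) -> int:
    """Smallest n of pairs whose exact noncentral-t power meets the target.

    With d = 0.50, alpha = 0.05 and power = 0.90 this returns 44 pairs.
    """
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if paired_ttest_power(d, n, alpha) >= power:
            return n
    raise ValueError("requested power unattainable within the search bound")


# ---------------------------------------------------------------------------
# CIN rule


def classify_cin(
    creatinine_baseline: float, creatinine_followup: float, hours_elapsed: float
) -> bool:
    """Contrast-induced nephropathy: creatinine rise > 0.5 mg/dL or > 25%
    within 72 hours (strict inequalities)."""
    if creatinine_baseline <= 0 or creatinine_followup <= 0:
        raise ValueError("creatinine values must be positive")
    if hours_elapsed < 0:
        raise ValueError("hours_elapsed must be non-negative")
    if hours_elapsed > 72:
        return False
    delta = creatinine_followup - creatinine_baseline
    return bool(delta > 0.5 or delta / creatinine_baseline > 0.25)


# ---------------------------------------------------------------------------
# aggregate report


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement layer for one matched endpoint."""

    label: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    paired: PairedTestResult
    r: float
    r2: float
    icc: ICCResult
    bland_altman: BlandAltmanResult


def agreement_report(a, b, label: str = "") -> AgreementReport:
    a_, b_ = _check_pairs(a, b, min_n=3)
    r, r2 = correlation(a_, b_)
    return AgreementReport(
        label=label,
        n=a_.size,
        mean_a=float(np.mean(a_)),
        sd_a=float(np.std(a_, ddof=1)),
        mean_b=float(np.mean(b_)),
        sd_b=float(np.std(b_, ddof=1)),
        paired=paired_compare(a_, b_),
        r=r,
        r2=r2,
        icc=icc_agreement(a_, b_),
        bland_altman=bland_altman(a_, b_),
    )
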
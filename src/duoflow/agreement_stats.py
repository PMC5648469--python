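"""Method-agreement statistics for paired perfusion measurements.

Pearson correlation with its two-sided p-value, the ordinary least-squares
regression line of the test method on the reference method, Bland-Altman
bias with limits of agreement at bias +/- 2 SD, the paired Student t-test,
and 2x2 contingency tables against a reference labelling.  The difference
convention is reference minus test (here: PET minus CMR), and regression
puts the reference method on x.  p-values are descriptive; no multiplicity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "pearson",
    "fit_line",
    "bland_altman",
    "paired_ttest",
    "contingency_2x2",
    "rate_pressure_product",
    "agreement_report",
    "plot_agreement",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """x: reference-method values (PET); y: test-method values (CMR)."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple = ()
    unit: str = "ml/min/g"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and equal length")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing pairs are not allowed")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class AgreementReport:
    r: float
    p_r: float
    slope: float
    intercept: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    unit: str = "ml/min/g"

    def __post_init__(self) -> None:
        if not np.isnan(self.r) and not -1.0000001 <= self.r <= 1.0000001:
            raise ValueError("r outside [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def pearson(pairs: PairedMeasurements):
    """Sample Pearson r with the two-sided p from the t-transform (n-2 df)."""
    if pairs.n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.std(pairs.x) == 0 or np.std(pairs.y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(pairs.x, pairs.y)
    return float(res.statistic), float(res.pvalue)


def fit_line(pairs: PairedMeasurements):
    """OLS of y (test method) on x (reference method): (slope, intercept)."""
    if pairs.n < 2:
        raise ValueError("need n >= 2 for a regression line")
    if np.std(pairs.x) == 0:
        raise ValueError("constant x: regression undefined")
    res = stats.linregress(pairs.x, pairs.y)
    return float(res.slope), float(res.intercept)


def bland_altman(pairs: PairedMeasurements, k: float = 2.0):
    """Bias (mean of x - y), sample SD of the differences, and the limits of
    agreement bias -/+ k*SD (k = 2 to match the study's figure convention).

    Returns ``(bias, sd_diff, (loa_low, loa_high))``.
    """
    if pairs.n < 2:
        raise ValueError("need n >= 2 for Bland-Altman")
    d = pairs.x - pairs.y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, (bias - k * sd, bias + k * sd)


def paired_ttest(a, b):
    """Two-sided paired Student t-test; returns (t, p).

    Zero-variance differences give t = 0, p = 1 when the mean difference is
    zero; a nonzero mean with zero variance is reported as (inf-signed t,
    p = 0.0) rather than raising.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length 1-D samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.isclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def contingency_2x2(test_positive, reference_positive) -> np.ndarray:
    """Cross-tabulate test (rows) against reference (columns).

    Layout ``[[++, +-], [-+, --]]``: row 0 = test positive, column 0 =
    reference positive.
    """
    t = np.asarray(test_positive, bool)
    r = np.asarray(reference_positive, bool)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("flag vectors must be 1-D and equal length")
    return np.array([
        [int(np.sum(t & r)), int(np.sum(t & ~r))],
        [int(np.sum(~t & r)), int(np.sum(~t & ~r))],
    ])


def rate_pressure_product(heart_rate, systolic_bp):
    """RPP = heart rate (bpm) x systolic blood pressure (mmHg)."""
    hr = np.asarray(heart_rate, float)
    bp = np.asarray(systolic_bp, float)
    if np.any(hr <= 0) or np.any(bp <= 0):
        raise ValueError("heart rate and systolic pressure must be > 0")
    out = hr * bp
    return float(out) if out.ndim == 0 else out


def agreement_report(pairs: PairedMeasurements, k: float = 2.0) -> AgreementReport:
    """Full agreement panel: correlation, regression line and Bland-Altman."""
    r, p_r = pearson(pairs)
    slope, intercept = fit_line(pairs)
    bias, sd, (lo, hi) = bland_altman(pairs, k=k)
    return AgreementReport(r=r, p_r=p_r, slope=slope, intercept=intercept,
                           bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
                           n=pairs.n, unit=pairs.unit)


def plot_agreement(pairs: PairedMeasurements, report: AgreementReport,
                   out_path, title: str = ""):
    """Scatter-with-regression plus Bland-Altman difference plot (one file)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(pairs.x, pairs.y, s=12, alpha=0.7)
    lim = [0, max(pairs.x.max(), pairs.y.max()) * 1.05]
    ax1.plot(lim, lim, "k-", lw=1, label="identity")
    xs = np.asarray(lim)
    ax1.plot(xs, report.slope * xs + report.intercept, "k--", lw=1,
             label=f"y = {report.slope:.2f}x + {report.intercept:.2f}")
    ax1.set_xlabel(f"reference ({pairs.unit})")
    ax1.set_ylabel(f"test ({pairs.unit})")
    ax1.legend(fontsize=8)
    ax1.set_title(f"{title} r = {report.r:.2f}")

    mean = (pairs.x + pairs.y) / 2
    diff = pairs.x - pairs.y
    ax2.scatter(mean, diff, s=12, alpha=0.7)
    ax2.axhline(report.bias, color="k")
    for y in (report.loa_low, report.loa_high):
        ax2.axhline(y, color="k", ls="--")
    ax2.set_xlabel(f"mean ({pairs.unit})")
    ax2.set_ylabel(f"difference ({pairs.unit})")
    ax2.set_title(f"bias {report.bias:+.2f} ± {report.sd_diff:.2f}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
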
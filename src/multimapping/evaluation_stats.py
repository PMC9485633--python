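"""Method-agreement statistics: ROI measurement, Bland–Altman, paired t
tests with Bonferroni correction, Pearson correlation and intraclass
correlation.

These are the statistics used to compare two quantitative mapping methods
measured on the same subjects or segments: bias and limits of agreement
(Bland–Altman), squared Pearson correlation, paired two-tailed t tests at
a Bonferroni-corrected threshold, and the absolute-agreement single-
measure intraclass correlation coefficient ICC(A,1) computed from two-way
ANOVA mean squares (McGraw & Wong convention), with an F-based confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "AgreementSummary",
    "roi_stats",
    "bland_altman",
    "paired_t_bonferroni",
    "pearson_r2",
    "icc_absolute_agreement",
    "shapiro_normality",
]


@dataclass
class PairedMeasurements:
    """Per-subject (or per-segment) values of two methods, A and B."""

    a: np.ndarray
    b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.a.size != self.b.size:
            raise ValueError("paired measurements must have equal length")
        if self.a.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(~np.isfinite(self.a)) or np.any(~np.isfinite(self.b)):
            raise ValueError("missing/non-finite values must be removed before pairing")

    @property
    def n(self) -> int:
        return self.a.size

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass
class AgreementSummary:
    """Bland–Altman bias and limits of agreement, plus optional test results."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int
    r2: float | None = None
    t_statistic: float | None = None
    p_value: float | None = None
    significant_after_bonferroni: bool | None = None


def roi_stats(map_data, mask: np.ndarray) -> tuple[float, float, int]:
    """Mean, SD (ddof=1) and count over masked valid pixels.

    ``map_data`` may be a ParameterMap or a plain 2D array; NaN (invalid)
    pixels inside the mask are excluded from the statistics and the count.
    """
    data = np.asarray(getattr(map_data, "data", map_data), dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map shape {data.shape}")
    vals = data[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid pixels in ROI")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd, int(vals.size)


def bland_altman(pairs: PairedMeasurements) -> AgreementSummary:
    """Bias (mean difference) and 1.96-SD limits of agreement."""
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementSummary(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        n=pairs.n,
    )


def paired_t_bonferroni(
    pairs: PairedMeasurements, n_comparisons: int = 4
) -> tuple[float, float, bool]:
    """Two-tailed paired t test at a Bonferroni-corrected threshold.

    Returns (t, p, significant) with ``significant iff p < 0.05 / n_comparisons``.
    Zero-variance differences: p = 1 if the mean difference is zero
    (identical methods), else p = 0 (degenerate certainty).
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    d = pairs.differences
    threshold = 0.05 / n_comparisons
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return 0.0, 1.0, False
        return np.inf, 0.0, True
    t, p = sps.ttest_rel(pairs.a, pairs.b)
    return float(t), float(p), bool(p < threshold)


def pearson_r2(pairs: PairedMeasurements) -> float:
    """Squared Pearson correlation coefficient."""
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(pairs.a) == 0 or np.std(pairs.b) == 0:
        raise ValueError("zero variance in one of the variables")
    r, _ = sps.pearsonr(pairs.a, pairs.b)
    return float(r * r)


def shapiro_normality(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk normality test (informational)."""
    w, p = sps.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)


def icc_absolute_agreement(
    ratings: np.ndarray,
    confidence: float = 0.95,
    average_measure: bool = False,
) -> tuple[float, float, float]:
    """Absolute-agreement two-way ICC from ANOVA mean squares.

    ``ratings`` is an (n subjects x k raters) matrix with no missing
    cells.  The default is the single-measure form

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR/MSC/MSE the rows/columns/error mean squares of the two-way
    ANOVA.  ``average_measure=True`` returns ICC(A,k).  The confidence
    interval follows the McGraw & Wong F-based construction.  A matrix of
    identical values returns (1, 1, 1) by convention.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (subjects >= 2) x (raters >= 2)")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings must have no missing cells")
    n, k = x.shape
    if np.ptp(x) == 0:
        return 1.0, 1.0, 1.0

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if average_measure:
        icc = (msr - mse) / (msr + (msc - mse) / n)
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # F-based CI for the single-measure form (McGraw & Wong); the
    # average-measure CI is the Spearman-Brown transform of it.
    alpha = 1.0 - confidence
    icc1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    a = (k * icc1) / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
    b = 1.0 + (k * icc1 * (n - 1.0)) / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
    if not np.isfinite(a) or mse == 0:
        lo1, hi1 = 1.0, 1.0
    else:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    if average_measure:
        def sb(r):  # Spearman-Brown step-up
            denom = 1.0 + (k - 1) * r
            return k * r / denom if denom != 0 else 1.0
        return float(icc), float(sb(lo1)), float(sb(hi1))
    return float(icc), float(lo1), float(hi1)
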
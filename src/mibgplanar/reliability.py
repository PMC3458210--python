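"""Reliability statistics: two-way mixed ICC, Bland-Altman, planning.

The intraclass correlation coefficient is computed from the explicit two-way
(subject x rater) ANOVA mean squares, in the McGraw & Wong nomenclature:

* consistency, single measures   ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)
* consistency, average measures  ICC(C,k) = (MSR - MSE) / MSR
* absolute agreement variants additionally involve the rater mean square MSC.

``measures="single"`` rates one observer's measurement (used for
intra-observer analyses), ``measures="average"`` the mean over the k
observers (inter-observer analyses).  95 % confidence intervals use exact
F-distribution bounds for the consistency definitions and the McGraw-Wong
approximation for absolute agreement.

Qualitative interpretation follows the conventional bins: ICC < 0.49 poor,
0.49-0.59 fair, 0.60-0.74 good, > 0.74 excellent; boundary values between
printed bins are resolved with contiguous half-open intervals
[0.49, 0.60) and [0.60, 0.75) so that every estimate classifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObserverMeasurementTable",
    "ReliabilityResult",
    "BlandAltmanResult",
    "icc_two_way_mixed",
    "classify_icc",
    "bland_altman",
    "filter_low_delayed_hm",
    "required_sample_size",
]

#: threshold defining the "very low" delayed H/M subgroup (severe denervation)
LOW_DELAYED_HM_THRESHOLD = 1.4


@dataclass
class ObserverMeasurementTable:
    """An n_subjects x k_raters matrix of one measurand (complete cases only)."""

    values: np.ndarray
    measurand: str = ""
    rater_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("measurement table must be 2-D (subjects x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 raters, got {n} x {k}")
        if np.isnan(self.values).any():
            raise ValueError("measurement table has missing cells; complete cases required")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    measures: str  # "single" | "average"
    definition: str  # "consistency" | "absolute"
    qualitative_class: str
    n_subjects: int
    k_raters: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 95 % limits of agreement for paired measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    pair_means: np.ndarray
    differences: np.ndarray


def _mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way crossed ANOVA mean squares (rows = subjects, cols = raters)."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = values - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def classify_icc(icc: float) -> str:
    """Qualitative class of an ICC estimate (poor/fair/good/excellent)."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.49:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def icc_two_way_mixed(
    table: ObserverMeasurementTable,
    measures: str = "single",
    definition: str = "consistency",
    alpha: float = 0.05,
) -> ReliabilityResult:
    """Two-way mixed-model ICC with a ``1 - alpha`` confidence interval.

    Degenerate tables are handled explicitly: if every value is identical the
    ICC is defined as 1 (with a warning); if the between-subject variance is
    zero but measurements disagree, the ICC is 0 (with a warning).
    """
    if measures not in ("single", "average"):
        raise ValueError("measures must be 'single' or 'average'")
    if definition not in ("consistency", "absolute"):
        raise ValueError("definition must be 'consistency' or 'absolute'")

    x = table.values
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)

    if np.ptp(x) == 0:
        warnings.warn("all measurements identical; ICC defined as 1", stacklevel=2)
        return ReliabilityResult(1.0, 1.0, 1.0, measures, definition, classify_icc(1.0), n, k)
    if msr == 0:
        warnings.warn("zero between-subject variance; ICC defined as 0", stacklevel=2)
        return ReliabilityResult(0.0, 0.0, 0.0, measures, definition, classify_icc(0.0), n, k)

    df_r = n - 1
    df_e = (n - 1) * (k - 1)

    if definition == "consistency":
        if measures == "single":
            icc = (msr - mse) / (msr + (k - 1) * mse)
        else:
            icc = (msr - mse) / msr
        if mse == 0:
            ci = (1.0, 1.0)
            icc = 1.0
        else:
            fobs = msr / mse
            f_low = fobs / stats.f.ppf(1 - alpha / 2, df_r, df_e)
            f_up = fobs * stats.f.ppf(1 - alpha / 2, df_e, df_r)
            if measures == "single":
                ci = ((f_low - 1) / (f_low + k - 1), (f_up - 1) / (f_up + k - 1))
            else:
                ci = (1 - 1 / f_low, 1 - 1 / f_up)
    else:  # absolute agreement, McGraw & Wong
        if measures == "single":
            icc = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        else:
            icc = (msr - mse) / (msr + (msc - mse) / n)
        if mse == 0 and msc == 0:
            ci = (1.0, 1.0)
            icc = 1.0
        else:
            # Satterthwaite df for the denominator combination
            icc1 = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
            a = k * icc1 / (n * (1 - icc1)) if icc1 < 1 else np.inf
            b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1)) if icc1 < 1 else np.inf
            if np.isinf(a) or np.isinf(b):
                ci = (1.0, 1.0)
            else:
                num = (a * msc + b * mse) ** 2
                den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / df_e
                v = num / den if den > 0 else df_e
                f1 = stats.f.ppf(1 - alpha / 2, df_r, v)
                f2 = stats.f.ppf(1 - alpha / 2, v, df_r)
                low1 = n * (msr - f1 * mse) / (
                    f1 * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                up1 = n * (f2 * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f2 * msr
                )
                if measures == "single":
                    ci = (low1, up1)
                else:
                    ci = (
                        low1 * k / (1 + (k - 1) * low1),
                        up1 * k / (1 + (k - 1) * up1),
                    )

    ci_low, ci_high = float(min(ci)), float(max(ci))
    ci_low = max(ci_low, -1.0)
    ci_high = min(ci_high, 1.0)
    icc = float(icc)
    return ReliabilityResult(
        icc=icc,
        ci_low=ci_low,
        ci_high=ci_high,
        measures=measures,
        definition=definition,
        qualitative_class=classify_icc(icc),
        n_subjects=n,
        k_raters=k,
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired measurement vectors.

    Differences are ``x - y``; limits of agreement are the mean difference
    +/- 1.96 sample SDs (n-1 denominator).  The per-pair means and
    differences are returned for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        n=int(x.size),
        pair_means=(x + y) / 2.0,
        differences=d,
    )


def filter_low_delayed_hm(
    records: pd.DataFrame,
    threshold: float = LOW_DELAYED_HM_THRESHOLD,
    reference_column: str = "hm_delayed_ref",
) -> pd.DataFrame:
    """Select the severe-denervation subgroup: reference delayed H/M <= threshold.

    The selection uses one designated reference observer's first delayed H/M
    measurement per subject (``reference_column``); the boundary value is
    included.  Records with a missing reference measurement are rejected.
    """
    if reference_column not in records.columns:
        raise KeyError(f"records lack reference column {reference_column!r}")
    ref = records[reference_column]
    if ref.isna().any():
        bad = records.index[ref.isna()].tolist()
        raise ValueError(f"missing reference delayed H/M for records {bad}")
    return records.loc[ref <= threshold]


def required_sample_size(icc0: float, ci_width: float, k: int, alpha: float = 0.05) -> int:
    """Smallest n whose large-sample 95 % CI for the ICC is no wider than ``ci_width``.

    Uses the asymptotic variance of the ICC estimator in a reliability design
    with k raters::

        var(icc_hat) = 2 (1 - rho)^2 (1 + (k-1) rho)^2 / (k (k-1) (n-1))

    and a symmetric normal interval ``icc0 +/- z * sqrt(var)``.
    """
    if not 0 < icc0 < 1:
        raise ValueError("icc0 must be in (0, 1)")
    if ci_width <= 0:
        raise ValueError("ci_width must be positive")
    if k < 2:
        raise ValueError("need at least 2 raters")
    z = stats.norm.ppf(1 - alpha / 2)
    var_unit = 2 * (1 - icc0) ** 2 * (1 + (k - 1) * icc0) ** 2 / (k * (k - 1))
    n_minus_1 = var_unit * (2 * z / ci_width) ** 2
    return max(2, int(np.ceil(n_minus_1 + 1)))
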
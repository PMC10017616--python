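"""Series-agreement statistics for paired per-patient measurements.

Given per-patient measurements of one metric (EAT volume in mL, mean
attenuation or noise in HU, or a histogram distance) on a reference series
(TNC) and a comparator series, this module computes:

* mean / median paired differences and percent differences — under two
  conventions, since printed percentages in agreement tables are often
  ambiguous: the per-patient convention ``mean((y−x)/x)·100`` (primary) and
  the ratio-of-means convention ``mean(y−x)/mean(x)·100``;
* an ordinary least-squares fit predicting the *reference* from the
  comparator, with R² = 1 − SS_res/SS_tot as the agreement measure
  (the reference is the response, so R² reads "fraction of reference
  variance explained by the comparator's linear prediction");
* a Shapiro-Wilk normality gate on the paired differences that selects the
  paired t-test (normal) or the Wilcoxon signed-rank test (non-normal),
  both two-sided;
* Bonferroni adjustment min(1, m·p) with a configurable family size m;
* mean-difference (Bland-Altman) plot data with bias ± 1.96·SD limits of
  agreement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PairedSample:
    """Patient-aligned measurement pairs (reference x, comparator y).

    Pairs with a missing value on either side are dropped on construction
    (pairwise exclusion); at least 3 complete pairs are required.
    """

    patient_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    metric: str = ""
    reference_label: str = ""
    comparator_label: str = ""

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.patient_ids) == len(self.x) == len(self.y)):
            raise ValueError("patient_ids, x and y must have equal lengths")
        keep = np.isfinite(self.x) & np.isfinite(self.y)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "%s %s vs %s: %d pair(s) excluded for missing values",
                self.metric, self.comparator_label, self.reference_label, n_dropped,
            )
            self.patient_ids = self.patient_ids[keep]
            self.x = self.x[keep]
            self.y = self.y[keep]
        if len(self.x) < 3:
            raise ValueError(f"need at least 3 complete pairs, have {len(self.x)}")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def diffs(self) -> np.ndarray:
        return self.y - self.x


@dataclass
class PairedDifferences:
    mean_diff: float
    median_diff: float
    pct_diff_primary: float          # mean of per-patient ratios, %
    pct_diff_ratio_of_means: float   # difference of means over mean reference, %


def paired_differences(sample: PairedSample) -> PairedDifferences:
    """Mean/median differences and percent differences under both conventions.

    Patients with a zero reference value are excluded from the per-patient
    percent convention (with a warning); they still contribute to the
    absolute and ratio-of-means quantities.
    """
    d = sample.diffs
    nonzero = sample.x != 0
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} patient(s) with zero reference excluded "
            "from per-patient percent difference", stacklevel=2,
        )
    if nonzero.any():
        pct_primary = float(np.mean(d[nonzero] / sample.x[nonzero]) * 100.0)
    else:
        pct_primary = float("nan")
    mean_x = float(sample.x.mean())
    pct_rom = float(d.mean() / mean_x * 100.0) if mean_x != 0 else float("nan")
    return PairedDifferences(
        mean_diff=float(d.mean()),
        median_diff=float(np.median(d)),
        pct_diff_primary=pct_primary,
        pct_diff_ratio_of_means=pct_rom,
    )


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    degenerate: bool = False


def regression_fit(sample: PairedSample) -> RegressionFit:
    """OLS with the reference as response: x ≈ slope·y + intercept.

    R² = 1 − SS_res/SS_tot. A constant reference (SS_tot = 0) is flagged
    degenerate with a missing R²; a constant comparator (zero predictor
    variance) is an error.
    """
    if np.var(sample.y) == 0:
        raise ValueError("comparator has zero variance; regression undefined")
    if np.var(sample.x) == 0:
        warnings.warn("reference is constant (SS_tot = 0); R^2 undefined", stacklevel=2)
        res = stats.linregress(sample.y, sample.x)
        return RegressionFit(float(res.slope), float(res.intercept), float("nan"),
                             degenerate=True)
    res = stats.linregress(sample.y, sample.x)
    pred = res.slope * sample.y + res.intercept
    ss_res = float(np.sum((sample.x - pred) ** 2))
    ss_tot = float(np.sum((sample.x - sample.x.mean()) ** 2))
    return RegressionFit(float(res.slope), float(res.intercept), 1.0 - ss_res / ss_tot)


def normality_gate(diffs: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """Shapiro-Wilk on the paired differences; normal iff p > alpha.

    Constant differences make the test undefined; the gate then returns
    (False, nan) with a warning, routing the comparison to the
    distribution-free test.
    """
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 3:
        raise ValueError("need at least 3 differences for the normality test")
    if np.ptp(diffs) == 0:
        warnings.warn("constant differences: Shapiro-Wilk undefined, gate -> non-normal",
                      stacklevel=2)
        return False, float("nan")
    with warnings.catch_warnings():
        # scipy warns for n > 5000 (p-value accuracy), not a problem for gating
        warnings.simplefilter("ignore")
        stat, p = stats.shapiro(diffs)
    return bool(p > alpha), float(p)


@dataclass
class PairedTestResult:
    test: str           # "t" or "wilcoxon"
    statistic: float
    p: float
    degenerate: bool = False


def paired_test(sample: PairedSample, is_normal: bool) -> PairedTestResult:
    """Two-sided paired t-test (normal gate) or Wilcoxon signed-rank (otherwise).

    All-zero differences leave both tests undefined; the result then carries
    p = 1 with a degenerate flag (there is no evidence of any difference).
    """
    d = sample.diffs
    if np.all(d == 0):
        return PairedTestResult("wilcoxon" if not is_normal else "t",
                                float("nan"), 1.0, degenerate=True)
    if is_normal:
        if np.ptp(d) == 0:
            # nonzero constant differences: zero variance, t undefined
            warnings.warn("zero-variance differences: t statistic undefined", stacklevel=2)
            return PairedTestResult("t", float("nan"), 0.0, degenerate=True)
        stat, p = stats.ttest_rel(sample.y, sample.x)
        return PairedTestResult("t", float(stat), float(p))
    stat, p = stats.wilcoxon(sample.y, sample.x)
    return PairedTestResult("wilcoxon", float(stat), float(p))


def adjust_bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: each p becomes min(1, m·p).

    ``m`` defaults to the number of p-values; it is configurable because the
    comparison family may be defined over a whole results table rather than
    the vector at hand.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


@dataclass
class MeanDifferenceData:
    """Bland-Altman-style plot data: per-patient means and differences."""

    table: pd.DataFrame   # columns: patient_id, mean, diff
    bias: float
    loa_lower: float
    loa_upper: float


def mean_difference_data(sample: PairedSample) -> MeanDifferenceData:
    """Per-patient (mean, difference) pairs with bias ± 1.96·SD limits."""
    d = sample.diffs
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    table = pd.DataFrame(
        {"patient_id": sample.patient_ids,
         "mean": (sample.x + sample.y) / 2.0,
         "diff": d}
    )
    return MeanDifferenceData(table, bias, bias - 1.96 * sd, bias + 1.96 * sd)


@dataclass
class AgreementReport:
    """Full agreement summary for one (metric, reference, comparator) pair."""

    metric: str
    reference_label: str
    comparator_label: str
    n: int
    differences: PairedDifferences
    regression: RegressionFit | None
    shapiro_p: float
    is_normal: bool
    test: PairedTestResult
    p_adjusted: float = float("nan")
    mean_difference: MeanDifferenceData = field(default=None, repr=False)


def compare_pair(sample: PairedSample, alpha: float = 0.05) -> AgreementReport:
    """Run the full agreement analysis on one paired sample.

    The Bonferroni-adjusted p is filled in afterwards by the caller, which
    knows the comparison family (see :func:`adjust_bonferroni`).
    """
    diffs = paired_differences(sample)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reg = regression_fit(sample)
    except ValueError:
        reg = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        is_normal, shapiro_p = normality_gate(sample.diffs, alpha=alpha)
        test = paired_test(sample, is_normal)
    return AgreementReport(
        metric=sample.metric,
        reference_label=sample.reference_label,
        comparator_label=sample.comparator_label,
        n=sample.n,
        differences=diffs,
        regression=reg,
        shapiro_p=shapiro_p,
        is_normal=is_normal,
        test=test,
        mean_difference=mean_difference_data(sample),
    )
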
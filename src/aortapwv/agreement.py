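"""Paired method-agreement statistics.

For a method under test against a gold standard (per-subject paired values)
this module computes the standard comparison battery: Pearson correlation,
coefficient of variation (SD of the paired differences over the mean of all
measurements), mean unsigned error relative to the reference, the paired
t-test with the t-based 95% CI of the mean difference, and Bland-Altman
limits of agreement.  Differences between the correlations of two methods
with a common gold standard are tested by the interaction term of a pooled
linear regression (outcome = method measurements; predictors = reference,
method indicator, reference x method), which contrasts the two regression
slopes; Steiger's z-test for dependent correlations is available as a
labeled alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

from .errors import DegenerateStatisticsError, PairingError, SampleSizeError

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "agreement",
    "ci95_from_summary",
    "CorrelationComparison",
    "compare_method_correlations",
    "steiger_z_dependent",
]


@dataclass(frozen=True)
class PairedSeries:
    """Per-subject measurements of a method under test and a gold standard."""

    test_values: np.ndarray
    reference_values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.test_values, dtype=float)
        r = np.asarray(self.reference_values, dtype=float)
        object.__setattr__(self, "test_values", t)
        object.__setattr__(self, "reference_values", r)
        if t.shape != r.shape or t.ndim != 1:
            raise PairingError("test and reference must be equal-length 1-D series")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise PairingError("values must be finite")
        if self.labels is not None and len(self.labels) != t.size:
            raise PairingError("labels length mismatch")

    @property
    def n(self) -> int:
        return int(self.test_values.size)


@dataclass(frozen=True)
class AgreementReport:
    """Full paired-comparison statistic set for one method pair."""

    pearson_r: float
    p_r: float
    cov_pct: float
    mue_pct: float
    mue_sd_pct: float
    mean_diff: float
    sd_diff: float
    ci95_lo: float
    ci95_hi: float
    p_ttest: float
    loa_lo: float
    loa_hi: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def ci95_from_summary(mean_diff: float, sd_diff: float, n: int) -> tuple[float, float]:
    """t-based 95% CI of a mean difference from its summary statistics.

    mean_diff +- t(0.975, n-1) * sd_diff / sqrt(n).
    """
    if n < 2:
        raise SampleSizeError("need n >= 2 for a confidence interval")
    if sd_diff < 0:
        raise DegenerateStatisticsError("sd_diff must be >= 0")
    half = st.t.ppf(0.975, n - 1) * sd_diff / math.sqrt(n)
    return (mean_diff - half, mean_diff + half)


def agreement(series: PairedSeries, *, error_units: str = "percent") -> AgreementReport:
    """Agreement battery of a method under test against its reference.

    ``error_units="percent"`` (default) reports the mean unsigned error as
    mean over subjects of 100*|test-ref|/ref; ``"absolute"`` reports it in
    measurement units.

    Raises
    ------
    SampleSizeError
        n < 3.
    DegenerateStatisticsError
        Zero variance in either series (correlation undefined), or a zero
        reference value with percent errors.
    """
    n = series.n
    if n < 3:
        raise SampleSizeError(f"need n >= 3 paired subjects, got {n}")
    t, r = series.test_values, series.reference_values
    if np.std(t) == 0 or np.std(r) == 0:
        raise DegenerateStatisticsError("zero variance: correlation undefined")
    pr = st.pearsonr(t, r)
    d = t - r
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    grand_mean = float(np.mean(np.concatenate([t, r])))
    if grand_mean == 0:
        raise DegenerateStatisticsError("zero grand mean: COV undefined")
    cov_pct = 100.0 * sd_diff / grand_mean
    if error_units == "percent":
        if np.any(r == 0):
            raise DegenerateStatisticsError("zero reference value: percent error undefined")
        ue = 100.0 * np.abs(d) / r
    elif error_units == "absolute":
        ue = np.abs(d)
    else:
        raise ValueError("error_units must be 'percent' or 'absolute'")
    if sd_diff == 0:
        p_ttest = float("nan")
    else:
        p_ttest = float(st.ttest_rel(t, r).pvalue)
    lo, hi = ci95_from_summary(mean_diff, sd_diff, n)
    return AgreementReport(
        pearson_r=float(pr.statistic),
        p_r=float(pr.pvalue),
        cov_pct=float(cov_pct),
        mue_pct=float(np.mean(ue)),
        mue_sd_pct=float(np.std(ue, ddof=1)),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        ci95_lo=float(lo),
        ci95_hi=float(hi),
        p_ttest=p_ttest,
        loa_lo=mean_diff - 1.96 * sd_diff,
        loa_hi=mean_diff + 1.96 * sd_diff,
        n=n,
    )


@dataclass(frozen=True)
class CorrelationComparison:
    """Interaction-regression contrast of two methods against one reference."""

    p_value: float
    interaction_coef: float
    coefs: dict
    ses: dict


def _check_shared_reference(a: PairedSeries, b: PairedSeries) -> None:
    if a.n != b.n:
        raise PairingError("series must cover the same subjects")
    if not np.allclose(a.reference_values, b.reference_values):
        raise PairingError("reference values differ between series")
    if a.labels is not None and b.labels is not None and a.labels != b.labels:
        raise PairingError("subject labels differ between series")


def compare_method_correlations(
    series_a: PairedSeries, series_b: PairedSeries
) -> CorrelationComparison:
    """Test whether two methods relate differently to the same gold standard.

    The two methods' measurements are stacked as outcome; predictors are the
    reference value, a method indicator, and their interaction.  The returned
    p-value is the two-sided p of the interaction coefficient (a contrast of
    the two regression slopes on the gold standard).
    """
    _check_shared_reference(series_a, series_b)
    n = series_a.n
    df = pd.DataFrame(
        {
            "y": np.concatenate([series_a.test_values, series_b.test_values]),
            "ref": np.concatenate(
                [series_a.reference_values, series_b.reference_values]
            ),
            "method": np.concatenate([np.zeros(n), np.ones(n)]),
        }
    )
    fit = smf.ols("y ~ ref + method + ref:method", data=df).fit()
    p = float(fit.pvalues["ref:method"])
    if math.isnan(p) and abs(float(fit.params["ref:method"])) < 1e-12:
        # identical methods with an exactly-linear outcome: no evidence of
        # any slope difference
        p = 1.0
    return CorrelationComparison(
        p_value=p,
        interaction_coef=float(fit.params["ref:method"]),
        coefs={k: float(v) for k, v in fit.params.items()},
        ses={k: float(v) for k, v in fit.bse.items()},
    )


def steiger_z_dependent(
    series_a: PairedSeries, series_b: PairedSeries
) -> tuple[float, float]:
    """Steiger's z-test for two dependent correlations sharing one variable.

    Compares r(test_a, ref) with r(test_b, ref) accounting for
    r(test_a, test_b).  Provided as a labeled alternative to the default
    interaction-regression contrast (which tests slopes, not correlations);
    returns (z, two-sided p).
    """
    _check_shared_reference(series_a, series_b)
    n = series_a.n
    if n < 4:
        raise SampleSizeError("need n >= 4 for Steiger's z")
    r13 = float(st.pearsonr(series_a.test_values, series_a.reference_values).statistic)
    r23 = float(st.pearsonr(series_b.test_values, series_b.reference_values).statistic)
    r12 = float(st.pearsonr(series_a.test_values, series_b.test_values).statistic)
    if abs(r13 - r23) < 1e-15:
        return 0.0, 1.0
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    rbar = (r13 + r23) / 2
    denom = 2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r12) ** 3
    if denom <= 0:
        raise DegenerateStatisticsError("degenerate correlation structure")
    z = (r13 - r23) * math.sqrt((n - 1) * (1 + r12)) / math.sqrt(denom)
    p = 2 * (1 - st.norm.cdf(abs(z)))
    return z, float(p)
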
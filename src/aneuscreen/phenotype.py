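"""Two-group tests reconstructed from summary statistics and glycaemia calls.

Aneuploidy-model phenotyping in this pipeline typically starts from
published group summaries -- (mean, SEM, n) triples of fasting blood
glucose -- rather than per-animal raw values. For a Student or Welch
t test these triples are sufficient: the group SD is recovered as
``SEM * sqrt(n)`` and the test statistic is identical to the raw-data
test. The module also provides a trapezoidal AUC for glucose-tolerance
time courses, a rank-sum wrapper for raw per-animal tables (the
nonparametric companion test, which cannot be reconstructed from
summaries), and the percent-of-control effect summary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SummaryStat",
    "PhenotypeCall",
    "TimeSeries",
    "TestResult",
    "PHENOTYPE_LABELS",
    "two_group_test_from_summary",
    "classify_glycaemia",
    "auc_trapezoid",
    "percent_of_control",
    "rank_sum_test",
]

PHENOTYPE_LABELS = ("hyperglycaemic", "normoglycaemic", "hypoglycaemic")
TEST_VARIANTS = ("student_pooled", "welch")
AUC_BASELINES = ("none", "subtract_t0")


@dataclass(frozen=True)
class SummaryStat:
    """A (mean, SEM, n) group summary -- the unit of reconstructed tests."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got n={self.n}")
        if not (self.sem > 0 and math.isfinite(self.sem)):
            raise ValueError(f"SEM must be positive and finite, got {self.sem}")
        if not math.isfinite(self.mean):
            raise ValueError(f"mean must be finite, got {self.mean}")

    @property
    def sd(self) -> float:
        """Group standard deviation implied by the SEM: ``SEM * sqrt(n)``."""
        return self.sem * math.sqrt(self.n)

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStat":
        """Summarize raw per-subject values (ddof=1 SD)."""
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least 2 values to summarize a group")
        return cls(
            mean=float(arr.mean()),
            sem=float(arr.std(ddof=1) / math.sqrt(arr.size)),
            n=int(arr.size),
        )


@dataclass(frozen=True)
class PhenotypeCall:
    """A glycaemia classification with its supporting test evidence.

    ``direction`` is the sign of (case mean - control mean); the label is
    hyper- or hypoglycaemic only when the two-sided p falls below the
    significance level used at classification time.
    """

    label: str
    p_value: float
    direction: int

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPE_LABELS:
            raise ValueError(
                f"label must be one of {PHENOTYPE_LABELS}, got {self.label!r}"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")


@dataclass(frozen=True)
class TimeSeries:
    """Sampled measurement curve, e.g. an IPGTT glucose trace (minutes, mM)."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.times) != len(self.values):
            raise ValueError(
                f"times ({len(self.times)}) and values ({len(self.values)}) "
                "must have equal length"
            )
        if len(self.times) < 2:
            raise ValueError("a time series needs at least 2 points")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("sampling times must be strictly increasing")


class TestResult(NamedTuple):
    statistic: float
    df: float
    p_value: float


def two_group_test_from_summary(
    case: SummaryStat,
    control: SummaryStat,
    variant: str = "student_pooled",
) -> TestResult:
    """Unpaired two-sample t test computed from (mean, SEM, n) triples.

    ``student_pooled`` is the classical equal-variance Student test with
    ``df = n1 + n2 - 2``; ``welch`` uses per-group variances with the
    Satterthwaite degrees of freedom. The statistic is signed case minus
    control, the p-value two-sided. Numerically identical to the raw-data
    test applied to any sample with these moments.
    """
    if variant not in TEST_VARIANTS:
        raise ValueError(
            f"test variant must be one of {TEST_VARIANTS}, got {variant!r}"
        )
    equal_var = variant == "student_pooled"
    t_stat, p_value = stats.ttest_ind_from_stats(
        mean1=case.mean,
        std1=case.sd,
        nobs1=case.n,
        mean2=control.mean,
        std2=control.sd,
        nobs2=control.n,
        equal_var=equal_var,
    )
    if equal_var:
        df = float(case.n + control.n - 2)
    else:
        v1 = case.sd**2 / case.n
        v2 = control.sd**2 / control.n
        df = (v1 + v2) ** 2 / (v1**2 / (case.n - 1) + v2**2 / (control.n - 1))
    return TestResult(statistic=float(t_stat), df=df, p_value=float(p_value))


def classify_glycaemia(
    case: SummaryStat,
    control: SummaryStat,
    alpha: float = 0.05,
    variant: str = "student_pooled",
) -> PhenotypeCall:
    """Label a model hyper-, normo- or hypoglycaemic from group summaries.

    The call is hyperglycaemic when the case mean exceeds control with
    two-sided ``p < alpha``, hypoglycaemic for the opposite direction, and
    normoglycaemic otherwise.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    result = two_group_test_from_summary(case, control, variant=variant)
    diff = case.mean - control.mean
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    if result.p_value < alpha and direction > 0:
        label = "hyperglycaemic"
    elif result.p_value < alpha and direction < 0:
        label = "hypoglycaemic"
    else:
        label = "normoglycaemic"
    return PhenotypeCall(label=label, p_value=result.p_value, direction=direction)


def auc_trapezoid(series: TimeSeries, baseline: str = "none") -> float:
    """Trapezoidal area under a sampled curve (trait units x minutes).

    With ``baseline="subtract_t0"`` the t=0 value is subtracted first;
    negative increments are kept, so the area may be negative.
    """
    if baseline not in AUC_BASELINES:
        raise ValueError(
            f"baseline must be one of {AUC_BASELINES}, got {baseline!r}"
        )
    values = np.asarray(series.values, dtype=float)
    if baseline == "subtract_t0":
        values = values - values[0]
    return float(np.trapezoid(values, np.asarray(series.times, dtype=float)))


def percent_of_control(case_mean: float, control_mean: float) -> float:
    """Effect size as a percentage of the control group mean."""
    if not control_mean > 0:
        raise ValueError(
            f"control mean must be positive for a percent-of-control ratio, "
            f"got {control_mean}"
        )
    return 100.0 * case_mean / control_mean


def rank_sum_test(
    case_values: Sequence[float], control_values: Sequence[float]
) -> TestResult:
    """Mann-Whitney U test on raw per-subject values (two-sided).

    Provided for raw per-animal tables only; a rank test has no
    summary-statistic reconstruction. ``df`` is reported as NaN.
    """
    case_arr = np.asarray(case_values, dtype=float)
    control_arr = np.asarray(control_values, dtype=float)
    if case_arr.size < 2 or control_arr.size < 2:
        raise ValueError("both groups need at least 2 values for a rank test")
    u_stat, p_value = stats.mannwhitneyu(
        case_arr, control_arr, alternative="two-sided"
    )
    return TestResult(statistic=float(u_stat), df=float("nan"), p_value=float(p_value))
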
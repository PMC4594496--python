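"""Single-case inferential tests against a small normative sample.

Classical single-case neuropsychology statistics in the Crawford tradition:
a patient's score (or score discrepancy) is referred to a control sample of
size n through a t statistic with df = n - 1, treating the controls'
summary statistics as estimates rather than population values.

Implemented tests
-----------------
``rsdt``
    Revised Standardized Difference Test (Crawford & Garthwaite, 2005):
    does the patient's standardized discrepancy between two tasks fall
    outside the distribution of discrepancies in controls?  Uses the
    small-sample correction obtained from the method's quadratic solution.
``udt``
    Unstandardized Difference Test: the same question on the raw score
    difference, valid when the two tasks share a scale.  Serves as an
    internal cross-check of the RSDT.
``case_comparison``
    Two-case comparison: do two single cases differ on a score, scaled by
    the control sample's SD of that score?  z = (d1 - d2)/(sd * sqrt(2)),
    referred to t(n - 1).
``deficit_test``
    Crawford & Howell's single-score test of a deficit:
    t = (x - mean)/(sd * sqrt(1 + 1/n)).

All probabilities are two-tailed from Student's t with df = n - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _st

__all__ = [
    "NormativeSummary",
    "CaseScores",
    "TestResult",
    "p_from_t",
    "rsdt",
    "udt",
    "case_comparison",
    "deficit_test",
]


@dataclass(frozen=True)
class NormativeSummary:
    """Control sample summary for two tasks: means, SDs, correlation, n."""

    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    r: float
    n: int

    def __post_init__(self) -> None:
        if not (self.sd_x > 0 and self.sd_y > 0):
            raise ValueError("control SDs must be > 0")
        if not -1.0 < self.r < 1.0:
            raise ValueError("inter-task correlation must satisfy |r| < 1")
        if self.n < 2:
            raise ValueError("control sample size must be >= 2")

    @property
    def discrepancy_sd(self) -> float:
        """SD of the x - y discrepancy implied by the summary."""
        return math.sqrt(
            self.sd_x**2 + self.sd_y**2 - 2.0 * self.r * self.sd_x * self.sd_y
        )


@dataclass(frozen=True)
class CaseScores:
    """A single case's scores on the two tasks."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("case scores must be finite")


@dataclass(frozen=True)
class TestResult:
    """A single-case test statistic with df and two-tailed probability."""

    method: str
    statistic: float
    df: int
    p_two_tailed: float


def p_from_t(statistic: float, df: float) -> float:
    """Two-tailed tail probability of Student's t; symmetric in sign."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * _st.t.sf(abs(statistic), df))


def rsdt(case: CaseScores, norm: NormativeSummary) -> TestResult:
    """Revised Standardized Difference Test of a task discrepancy.

    The case's scores are standardized against the control means and SDs
    (z_x, z_y) and the small-sample-corrected statistic is the positive
    root of the method's quadratic, signed by z_x - z_y and referred to
    t(n - 1), two-tailed.
    """
    n, r = norm.n, norm.r
    z_x = (case.x - norm.mean_x) / norm.sd_x
    z_y = (case.y - norm.mean_y) / norm.sd_y
    dz = z_x - z_y
    a = (1.0 + r) * (1.0 - r**2)
    b = (1.0 - r) * (
        4.0 * (n - 1) ** 2 + 4.0 * (1.0 + r) * (n - 1) + (1.0 + r) * (5.0 + r)
    )
    c = -2.0 * dz**2 * (n * (n - 1) ** 2) / (n + 1)
    psi_sq = (-b + math.sqrt(b**2 - 4.0 * a * c)) / (2.0 * a)
    psi = math.copysign(math.sqrt(max(psi_sq, 0.0)), dz)
    return TestResult(
        method="rsdt",
        statistic=psi,
        df=n - 1,
        p_two_tailed=p_from_t(psi, n - 1),
    )


def udt(case: CaseScores, norm: NormativeSummary) -> TestResult:
    """Unstandardized Difference Test of a raw-score task discrepancy.

    t = [(x - y) - (mean_x - mean_y)] / [sd_d * sqrt(1 + 1/n)] with
    sd_d the control discrepancy SD; df = n - 1, two-tailed.
    """
    sd_d = norm.discrepancy_sd
    if sd_d <= 0:
        raise ValueError(
            "degenerate discrepancy variance: the control tasks are perfectly "
            "correlated with equal SDs"
        )
    t = ((case.x - case.y) - (norm.mean_x - norm.mean_y)) / (
        sd_d * math.sqrt(1.0 + 1.0 / norm.n)
    )
    return TestResult(
        method="udt",
        statistic=t,
        df=norm.n - 1,
        p_two_tailed=p_from_t(t, norm.n - 1),
    )


def case_comparison(d1: float, d2: float, sd_controls: float, n: int) -> TestResult:
    """Compare two single cases on a score, scaled by the controls' SD.

    z = (d1 - d2) / (sd_controls * sqrt(2)), referred to t(n - 1),
    two-tailed.  Antisymmetric in the two cases; the sign reports
    case1 minus case2.
    """
    if sd_controls <= 0:
        raise ValueError("control SD must be > 0")
    if n < 2:
        raise ValueError("control sample size must be >= 2")
    z = (d1 - d2) / (sd_controls * math.sqrt(2.0))
    return TestResult(
        method="case_comparison",
        statistic=z,
        df=n - 1,
        p_two_tailed=p_from_t(z, n - 1),
    )


def deficit_test(x: float, mean: float, sd: float, n: int) -> TestResult:
    """Single-score deficit test of a case against controls.

    t = (x - mean) / (sd * sqrt(1 + 1/n)), df = n - 1, two-tailed.
    """
    if sd <= 0:
        raise ValueError("control SD must be > 0")
    if n < 2:
        raise ValueError("control sample size must be >= 2")
    t = (x - mean) / (sd * math.sqrt(1.0 + 1.0 / n))
    return TestResult(
        method="deficit_test",
        statistic=t,
        df=n - 1,
        p_two_tailed=p_from_t(t, n - 1),
    )
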
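"""Cohort-level aggregation and the between-group risk-ratio comparison.

A group summary tabulates, for one cohort, how many assessments achieved
0..5 significant dilations and the proportion passing the >= 4-of-5 rule.
Success proportions between two groups are compared with the risk ratio
(ratio of proportions) using the Wald method on the log scale:

    rr     = (s1/n1) / (s2/n2)
    se_log = sqrt(1/s1 - 1/n1 + 1/s2 - 1/n2)
    CI     = exp(log rr -/+ z_conf * se_log)
    z      = log(rr) / se_log,   p = 2 * (1 - Phi(|z|))

No continuity correction is applied, so both groups must have at least one
success; callers with zero cells need an exact method, which is out of
scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .epoch_stats import SubjectResult
from .errors import ValidationError


@dataclass(frozen=True)
class GroupSummary:
    """Distribution of per-subject significant-dilation counts in one group."""

    group_label: str
    n_assessments: int
    n_success: int
    distribution: tuple[int, int, int, int, int, int]  # counts at 0..5 significant

    def __post_init__(self) -> None:
        if sum(self.distribution) != self.n_assessments:
            raise ValidationError("distribution must sum to n_assessments")
        if self.n_success != self.distribution[4] + self.distribution[5]:
            raise ValidationError("n_success must equal the mass at 4 and 5")

    @property
    def proportion(self) -> float:
        return self.n_success / self.n_assessments

    @property
    def percent_int(self) -> int:
        """Integer percentage, table style (e.g. 70)."""
        return round(100.0 * self.proportion)

    @property
    def percent_1dp(self) -> float:
        """One-decimal percentage, narrative style (e.g. 39.5)."""
        return round(100.0 * self.proportion, 1)


@dataclass(frozen=True)
class MeasurementRate:
    """A measurement-level dilation rate (dilations / task measurements)."""

    n_dilations: int
    n_measurements: int

    @property
    def fraction(self) -> float:
        return self.n_dilations / self.n_measurements

    @property
    def percent(self) -> float:
        """Percentage rounded to at most 2 decimals (e.g. 65, 46.67)."""
        return round(100.0 * self.fraction, 2)


@dataclass(frozen=True)
class RRResult:
    """Risk ratio with Wald log-scale confidence interval and z test."""

    rr: float
    se_log: float
    ci_low: float
    ci_high: float
    z: float
    p_two_sided: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValidationError("confidence interval must bracket the risk ratio")


def summarize_distribution(
    distribution: Mapping[int, int] | Sequence[int],
    group_label: str = "",
    k: int = 4,
) -> GroupSummary:
    """Build a group summary from counts of subjects by n_significant (0..5).

    Accepts either a mapping ``{n_significant: count}`` or a length-6
    sequence of counts.  Success means ``n_significant >= k``.
    """
    if isinstance(distribution, Mapping):
        counts = tuple(int(distribution.get(i, 0)) for i in range(6))
    else:
        counts = tuple(int(c) for c in distribution)
        if len(counts) != 6:
            raise ValidationError("distribution sequence must have 6 entries (0..5)")
    n = sum(counts)
    if n == 0:
        raise ValidationError("group must contain at least one assessment")
    n_success = sum(c for i, c in enumerate(counts) if i >= k)
    return GroupSummary(
        group_label=group_label,
        n_assessments=n,
        n_success=n_success,
        distribution=counts,
    )


def summarize_group(
    results: Sequence[SubjectResult], group_label: str = ""
) -> GroupSummary:
    """Summarize a list of per-subject results into a group summary."""
    if not results:
        raise ValidationError("cannot summarize an empty group")
    counts = [0] * 6
    for r in results:
        counts[r.n_significant] += 1
    n_success = sum(1 for r in results if r.command_following)
    return GroupSummary(
        group_label=group_label,
        n_assessments=len(results),
        n_success=n_success,
        distribution=tuple(counts),
    )


def measurement_rate(n_dilations: int, n_measurements: int) -> MeasurementRate:
    """Measurement-level dilation rate across all task epochs of a group."""
    if n_measurements <= 0:
        raise ValidationError("n_measurements must be positive")
    if not (0 <= n_dilations <= n_measurements):
        raise ValidationError("need 0 <= n_dilations <= n_measurements")
    return MeasurementRate(n_dilations=n_dilations, n_measurements=n_measurements)


def risk_ratio(
    s1: int, n1: int, s2: int, n2: int, conf: float = 0.95
) -> RRResult:
    """Wald log-scale risk ratio between two success proportions.

    ``s1/n1`` is the exposed (numerator) group.  Requires at least one
    success in each group; no continuity correction is implemented, so zero
    cells raise and the caller should use an exact method instead.
    """
    if not (0 < s1 <= n1) or not (0 < s2 <= n2):
        raise ValidationError(
            "risk_ratio requires 0 < successes <= total in both groups; "
            "zero-success groups need an exact method (not implemented)"
        )
    if not (0.0 < conf < 1.0):
        raise ValidationError("confidence level must be in (0, 1)")
    rr = (s1 / n1) / (s2 / n2)
    se_log = math.sqrt(1.0 / s1 - 1.0 / n1 + 1.0 / s2 - 1.0 / n2)
    log_rr = math.log(rr)
    z_conf = float(stats.norm.ppf(0.5 + conf / 2.0))
    if se_log > 0:
        z = log_rr / se_log
        p = 2.0 * float(stats.norm.sf(abs(z)))
    else:  # both proportions are 1: degenerate, no sampling variability
        z = 0.0
        p = 1.0
    return RRResult(
        rr=rr,
        se_log=se_log,
        ci_low=math.exp(log_rr - z_conf * se_log),
        ci_high=math.exp(log_rr + z_conf * se_log),
        z=z,
        p_two_sided=min(p, 1.0),
    )
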
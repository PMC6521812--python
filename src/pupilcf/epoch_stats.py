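"""Per-task dilation testing and the subject-level command-following rule.

The detection procedure: segment a recording by the paradigm schedule, then
for each of the five task epochs compare the diameter samples against those
of the flanking rest epochs with a rank test.  A task counts as a
significant dilation when the task median exceeds the rest median and the
Bonferroni-adjusted p-value falls below the significance level (default
0.01 adjusted over m = 5 tasks).  A subject shows command following when at
least k = 4 of the 5 tasks are significant dilations.

Two rank tests are available.  The default is the two-sample rank-sum
(Mann-Whitney) test of the task samples against the pooled rest samples,
which is well defined for the unpaired, unequal-length vectors the epochs
produce.  ``signed_rank_truncated`` instead trims both vectors symmetrically
to a common length, pairs them positionally and applies the Wilcoxon
signed-rank test; it mirrors analyses that name the signed-rank test for
this comparison, at the cost of an artificial pairing.

Exact null distributions are used for small samples (rank-sum when the
smaller group has <= 8 observations and there are no ties; signed-rank when
<= 12 non-zero differences), otherwise the tie-corrected normal
approximation without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .recording import Epoch, ParadigmSchedule, PupilRecording

RANK_SUM = "rank_sum"
SIGNED_RANK = "signed_rank_truncated"

EXACT_MAX_N_RANK_SUM = 8
EXACT_MAX_N_SIGNED_RANK = 12


@dataclass(frozen=True)
class EpochSamples:
    """Valid diameter samples falling inside one epoch."""

    epoch: Epoch
    diameters: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "diameters", np.asarray(self.diameters, dtype=float)
        )

    @property
    def n(self) -> int:
        return int(self.diameters.size)

    @property
    def median(self) -> float:
        return float(np.median(self.diameters)) if self.n else float("nan")


@dataclass(frozen=True)
class TaskComparison:
    """Statistical outcome of one task epoch against its flanking rests."""

    task_index: int
    n_task: int
    n_rest: int
    median_task_mm: float
    median_rest_mm: float
    statistic: float
    p_raw: float
    p_adj: float
    dilated: bool
    significant_dilation: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= self.p_adj <= 1.0):
            raise ValidationError(
                f"need 0 <= p_raw <= p_adj <= 1, got {self.p_raw}, {self.p_adj}"
            )
        if self.significant_dilation and not self.dilated:
            raise ValidationError("significant_dilation requires dilated")


@dataclass(frozen=True)
class SubjectResult:
    """Five task comparisons plus the binary command-following decision."""

    subject_id: str
    comparisons: tuple[TaskComparison, ...]
    n_significant: int
    command_following: bool


class RankTestResult(NamedTuple):
    statistic: float
    pvalue: float
    #: True when the test degenerated (e.g. all signed-rank differences zero).
    degenerate: bool = False


def segment(
    recording: PupilRecording, schedule: ParadigmSchedule
) -> list[EpochSamples]:
    """Assign every valid sample to its epoch by half-open interval.

    A sample exactly on an epoch boundary belongs to the later epoch.
    Invalid samples are dropped.  A recording shorter than the schedule span
    produces a warning; empty epochs surface as errors only downstream.
    """
    # The last sample of a complete recording lands up to one sampling
    # interval before the schedule end; only a real shortfall warns.
    shortfall_tol = 2.0 / recording.sampling_rate_hz
    if recording.samples and recording.duration_s < schedule.total_span_s - shortfall_tol:
        warnings.warn(
            f"recording {recording.subject_id!r} ends at {recording.duration_s:.1f} s "
            f"but the schedule spans {schedule.total_span_s:.1f} s",
            stacklevel=2,
        )
    times = np.array([s.time_s for s in recording.samples])
    diam = np.array([s.diameter_mm for s in recording.samples])
    valid = np.array([s.valid for s in recording.samples], dtype=bool)
    out: list[EpochSamples] = []
    for epoch in schedule.epochs:
        if times.size:
            mask = valid & (times >= epoch.start_s) & (times < epoch.end_s)
            out.append(EpochSamples(epoch=epoch, diameters=diam[mask]))
        else:
            out.append(EpochSamples(epoch=epoch, diameters=np.empty(0)))
    return out


def _symmetric_trim(v: np.ndarray, target: int) -> np.ndarray:
    """Trim a vector to ``target`` length, removing excess symmetrically.

    When the excess is odd, one more element is removed from the end than
    from the front.
    """
    excess = v.size - target
    front = excess // 2
    return v[front : front + target]


def rank_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = RANK_SUM,
    alternative: Literal["two_sided", "greater"] = "two_sided",
) -> RankTestResult:
    """Rank-based comparison of two diameter sample vectors.

    Parameters
    ----------
    x, y
        Non-empty sample vectors; ``alternative="greater"`` tests whether
        ``x`` is stochastically larger than ``y``.
    method
        ``"rank_sum"``: Mann-Whitney U with mid-ranks for ties; exact null
        distribution when ``min(len(x), len(y)) <= 8`` and no ties, else
        tie-corrected normal approximation without continuity correction.
        ``"signed_rank_truncated"``: both vectors symmetrically trimmed to
        the shorter length and paired positionally; zero differences are
        dropped; exact when <= 12 remaining pairs without tied magnitudes,
        else normal approximation without continuity correction.

    Returns
    -------
    RankTestResult
        ``(statistic, pvalue, degenerate)``; ``degenerate`` flags the
        all-zero-differences case where p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_test requires non-empty samples")
    scipy_alt = {"two_sided": "two-sided", "greater": "greater"}.get(alternative)
    if scipy_alt is None:
        raise ValidationError(f"unknown alternative {alternative!r}")

    if method == RANK_SUM:
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            # all observations tied: zero rank variance, no evidence either way
            return RankTestResult(x.size * y.size / 2.0, 1.0, degenerate=True)
        has_ties = np.unique(pooled).size < pooled.size
        use_exact = min(x.size, y.size) <= EXACT_MAX_N_RANK_SUM and not has_ties
        res = stats.mannwhitneyu(
            x,
            y,
            alternative=scipy_alt,
            method="exact" if use_exact else "asymptotic",
            use_continuity=False,
        )
        return RankTestResult(float(res.statistic), float(min(res.pvalue, 1.0)))

    if method == SIGNED_RANK:
        n = min(x.size, y.size)
        d = _symmetric_trim(x, n) - _symmetric_trim(y, n)
        d = d[d != 0.0]
        if d.size == 0:
            return RankTestResult(0.0, 1.0, degenerate=True)
        has_tied_mags = np.unique(np.abs(d)).size < d.size
        use_exact = d.size <= EXACT_MAX_N_SIGNED_RANK and not has_tied_mags
        res = stats.wilcoxon(
            d,
            alternative=scipy_alt,
            method="exact" if use_exact else "approx",
            correction=False,
        )
        return RankTestResult(float(res.statistic), float(min(res.pvalue, 1.0)))

    raise ValidationError(f"unknown rank test method {method!r}")


def compare_task(
    task: EpochSamples,
    rest_before: EpochSamples,
    rest_after: EpochSamples,
    alpha: float = 0.01,
    m: int = 5,
    method: str = RANK_SUM,
    alternative: Literal["two_sided", "greater"] = "two_sided",
    rest_pooling: Literal["pooled", "both"] = "pooled",
) -> TaskComparison:
    """Test one task epoch for significant dilation against flanking rests.

    ``rest_pooling="pooled"`` concatenates the two rest vectors and runs one
    test; ``"both"`` tests against each rest separately and keeps the larger
    (least favourable) p-value.  The adjusted p is ``min(1, m * p_raw)`` and
    a significant dilation additionally requires the task median to exceed
    the pooled rest median.
    """
    for name, es in (("task", task), ("rest_before", rest_before), ("rest_after", rest_after)):
        if es.n == 0:
            raise ValidationError(
                f"epoch {name!r} (task {task.epoch.index}) has no valid samples"
            )
    rest_pool = np.concatenate([rest_before.diameters, rest_after.diameters])
    median_task = task.median
    median_rest = float(np.median(rest_pool))

    if rest_pooling == "pooled":
        res = rank_test(task.diameters, rest_pool, method=method, alternative=alternative)
        statistic, p_raw = res.statistic, res.pvalue
    elif rest_pooling == "both":
        res_b = rank_test(task.diameters, rest_before.diameters, method=method, alternative=alternative)
        res_a = rank_test(task.diameters, rest_after.diameters, method=method, alternative=alternative)
        worse = max((res_b, res_a), key=lambda r: r.pvalue)
        statistic, p_raw = worse.statistic, worse.pvalue
    else:
        raise ValidationError(f"unknown rest_pooling {rest_pooling!r}")

    p_adj = min(1.0, m * p_raw)
    dilated = median_task > median_rest
    return TaskComparison(
        task_index=task.epoch.index,
        n_task=task.n,
        n_rest=int(rest_pool.size),
        median_task_mm=median_task,
        median_rest_mm=median_rest,
        statistic=statistic,
        p_raw=p_raw,
        p_adj=p_adj,
        dilated=dilated,
        significant_dilation=dilated and p_adj < alpha,
    )


def evaluate_subject(
    comparisons: Sequence[TaskComparison],
    subject_id: str = "",
    k: int = 4,
) -> SubjectResult:
    """Apply the >= k-of-5 command-following decision rule."""
    comparisons = tuple(comparisons)
    if len(comparisons) != 5:
        raise ValidationError(
            f"subject evaluation requires exactly 5 task comparisons, got {len(comparisons)}"
        )
    n_sig = sum(c.significant_dilation for c in comparisons)
    return SubjectResult(
        subject_id=subject_id,
        comparisons=comparisons,
        n_significant=n_sig,
        command_following=n_sig >= k,
    )


def analyze_recording(
    recording: PupilRecording,
    schedule: ParadigmSchedule,
    alpha: float = 0.01,
    m: int = 5,
    k: int = 4,
    method: str = RANK_SUM,
    alternative: Literal["two_sided", "greater"] = "two_sided",
    rest_pooling: Literal["pooled", "both"] = "pooled",
) -> SubjectResult:
    """Run the full per-subject pipeline: segment, test each task, decide."""
    epochs = segment(recording, schedule)
    comparisons = []
    # Schedule layout is rest-led: epochs alternate R T R T ... R, so task i
    # sits at position 2*i - 1 with its rests immediately adjacent.
    for i in range(5):
        pos = 2 * i + 1
        comparisons.append(
            compare_task(
                epochs[pos],
                epochs[pos - 1],
                epochs[pos + 1],
                alpha=alpha,
                m=m,
                method=method,
                alternative=alternative,
                rest_pooling=rest_pooling,
            )
        )
    return evaluate_subject(comparisons, subject_id=recording.subject_id, k=k)
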
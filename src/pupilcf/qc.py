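"""Baseline pupillary-function screening and run-chart quality control.

Participants are screened with an automated light-reflex measurement of
both eyes before the arithmetic paradigm.  The screen consumes the device's
Neurological Pupil index (NPi), a proprietary 0-5 summary score of
light-reflex integrity; values >= 3 are physiological, and the inter-eye
NPi difference must stay below 0.7.  The NPi is taken as a given number —
its internal computation is not reimplemented here.

Run charts (diameter against time with task/rest shading) support the
visual quality control applied to every recording before statistics.
Automated artifact flagging is provided but OFF by default: the reference
analysis deliberately runs on raw, uncleaned traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .recording import ParadigmSchedule, PupilRecording, PupilSample

NPI_MIN_PHYSIOLOGICAL = 3.0
NPI_MAX_INTER_EYE_DIFF = 0.7

#: Run-chart colour convention: arithmetic epochs green, rest epochs yellow.
EPOCH_COLORS = {"task": "green", "rest": "yellow"}

RULE_NPI_BELOW_3 = "npi_below_3"
RULE_INTER_EYE_DIFF = "inter_eye_diff"


@dataclass(frozen=True)
class BaselineScreen:
    """Light-reflex screening values for one eye.

    Only ``npi`` and ``baseline_diameter_mm`` enter the inclusion rule; the
    remaining device outputs are carried as pass-through metadata.
    """

    npi: float
    baseline_diameter_mm: float | None = None
    post_light_diameter_mm: float | None = None
    percent_change: float | None = None
    constriction_velocity: float | None = None
    dilation_velocity: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.npi <= 5.0):
            raise ValidationError(f"NPi must be in [0, 5], got {self.npi}")
        for name in ("baseline_diameter_mm", "post_light_diameter_mm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class QCDecision:
    """Inclusion decision with the identifiers of every violated rule."""

    include: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.include != (len(self.reasons) == 0):
            raise ValidationError("include must be true iff reasons is empty")


def screen_participant(left: BaselineScreen, right: BaselineScreen) -> QCDecision:
    """Apply the baseline inclusion rule to both eyes.

    A participant is included iff both NPi scores are >= 3 and the absolute
    inter-eye difference is strictly below 0.7 (a difference of exactly 0.7
    excludes).  ``reasons`` enumerates every violated rule.
    """
    reasons: list[str] = []
    if left.npi < NPI_MIN_PHYSIOLOGICAL or right.npi < NPI_MIN_PHYSIOLOGICAL:
        reasons.append(RULE_NPI_BELOW_3)
    if abs(left.npi - right.npi) >= NPI_MAX_INTER_EYE_DIFF:
        reasons.append(RULE_INTER_EYE_DIFF)
    return QCDecision(include=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class RunChartData:
    """Plot-ready series for a visual quality-control run chart.

    ``bands`` is one ``(start_s, end_s, kind, color)`` tuple per epoch;
    invalid samples carry NaN in ``diameters_mm`` so plotting leaves gaps
    rather than interpolating across dropouts.
    """

    subject_id: str
    times_s: np.ndarray
    diameters_mm: np.ndarray
    valid: np.ndarray
    bands: tuple[tuple[float, float, str, str], ...]


def run_chart(recording: PupilRecording, schedule: ParadigmSchedule) -> RunChartData:
    """Assemble run-chart data: diameter vs time with epoch shading metadata."""
    if not recording.samples:
        raise ValidationError("cannot build a run chart from an empty recording")
    times = np.array([s.time_s for s in recording.samples])
    diam = np.array([s.diameter_mm for s in recording.samples])
    valid = np.array([s.valid for s in recording.samples], dtype=bool)
    diam_masked = np.where(valid, diam, np.nan)
    bands = tuple(
        (e.start_s, e.end_s, e.kind, EPOCH_COLORS[e.kind]) for e in schedule.epochs
    )
    return RunChartData(
        subject_id=recording.subject_id,
        times_s=times,
        diameters_mm=diam_masked,
        valid=valid,
        bands=bands,
    )


def flag_artifacts(
    recording: PupilRecording,
    min_diameter_mm: float = 1.0,
    max_step_mm: float = 1.0,
) -> PupilRecording:
    """Mark dropout-like samples invalid without altering any diameter.

    A sample is flagged when its diameter falls below ``min_diameter_mm`` or
    when its absolute step from the previous *valid* sample exceeds
    ``max_step_mm``.  Idempotent; OFF by default in the pipeline because the
    reference analysis uses raw traces.
    """
    if min_diameter_mm <= 0 or max_step_mm <= 0:
        raise ValidationError("artifact thresholds must be positive")
    out: list[PupilSample] = []
    prev_valid_d: float | None = None
    for s in recording.samples:
        valid = s.valid
        if valid and s.diameter_mm < min_diameter_mm:
            valid = False
        if valid and prev_valid_d is not None and abs(s.diameter_mm - prev_valid_d) > max_step_mm:
            valid = False
        if valid:
            prev_valid_d = s.diameter_mm
        out.append(replace(s, valid=valid) if valid != s.valid else s)
    return replace(recording, samples=tuple(out))


def screen_cohort(
    screens: Sequence[tuple[str, BaselineScreen, BaselineScreen]],
) -> list[tuple[str, QCDecision]]:
    """Screen a whole cohort; returns ``(subject_id, decision)`` per entry."""
    return [(sid, screen_participant(left, right)) for sid, left, right in screens]
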
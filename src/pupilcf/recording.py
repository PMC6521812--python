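"""Domain types for pupil recordings and paradigm schedules, plus CSV I/O.

The recording interchange format is a deliberately small open CSV dialect
(one file per subject per session)::

    time_s,diameter_mm,valid
    0.0,4.61,1
    0.03333333333333333,NA,0

* ``time_s`` — seconds from recording start, strictly increasing.
* ``diameter_mm`` — pupil diameter in millimetres; the sentinel ``NA``
  marks dropout samples (blinks, eye movements, lid closure).
* ``valid`` — ``1``/``0``; a row with an ``NA`` diameter is always invalid.

Floats are written with ``repr`` (shortest round-trip representation), so a
write/read cycle reproduces the recording bit for bit.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .errors import ConfigurationError, FormatError, ValidationError

#: Arithmetic problems printed to participants, in presentation order.
MODERATE_PROBLEMS = ("21 × 22", "33 × 32", "55 × 54", "43 × 44", "81 × 82")
SIMPLE_PROBLEMS = ("4 × 46", "8 × 32", "3 × 67", "6 × 37", "7 × 43")

#: Default epoch durations in seconds per paradigm variant.
VARIANT_DURATIONS = {"moderate": (30.0, 30.0), "simple": (15.0, 15.0)}

CSV_HEADER = ("time_s", "diameter_mm", "valid")
NA_SENTINEL = "NA"

#: Nominal sampling rate of the handheld pupillometer (not specified by the
#: device vendor's public documentation; configurable everywhere it is used).
DEFAULT_SAMPLING_RATE_HZ = 30.0


@dataclass(frozen=True)
class PupilSample:
    """One timestamped diameter measurement of a single eye.

    Invalid samples represent dropouts; their diameter may be NaN (device
    reported nothing) or a retained measurement flagged by artifact QC.
    """

    time_s: float
    diameter_mm: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValidationError(f"sample time must be >= 0, got {self.time_s}")
        if self.valid and not (0.0 < self.diameter_mm <= 10.0):
            raise ValidationError(
                f"valid sample diameter must be in (0, 10] mm, got {self.diameter_mm}"
            )

    def __eq__(self, other: object) -> bool:
        # NaN diameters (device dropouts) must compare equal for round trips.
        if not isinstance(other, PupilSample):
            return NotImplemented
        same_d = (
            self.diameter_mm == other.diameter_mm
            or (math.isnan(self.diameter_mm) and math.isnan(other.diameter_mm))
        )
        return self.time_s == other.time_s and same_d and self.valid == other.valid


@dataclass(frozen=True)
class PupilRecording:
    """An ordered single-eye diameter trace for one subject session."""

    subject_id: str
    samples: tuple[PupilSample, ...]
    eye: Literal["left", "right"] = "right"
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ValidationError(f"eye must be 'left' or 'right', got {self.eye!r}")
        times = [s.time_s for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("sample times must be strictly increasing")
        object.__setattr__(self, "samples", tuple(self.samples))

    @property
    def duration_s(self) -> float:
        return self.samples[-1].time_s if self.samples else 0.0

    @property
    def n_valid(self) -> int:
        return sum(1 for s in self.samples if s.valid)


@dataclass(frozen=True)
class Epoch:
    """One half-open interval ``[start_s, end_s)`` of the paradigm.

    ``index`` is the ordinal within its own kind (task 1..5, rest 1..6);
    ``label`` holds the arithmetic problem shown during a task epoch.
    """

    kind: Literal["task", "rest"]
    index: int
    start_s: float
    end_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("task", "rest"):
            raise ValidationError(f"epoch kind must be task|rest, got {self.kind!r}")
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"epoch must have start_s < end_s, got [{self.start_s}, {self.end_s})"
            )

    def contains(self, t: float) -> bool:
        """Half-open membership: a boundary sample belongs to the later epoch."""
        return self.start_s <= t < self.end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ParadigmSchedule:
    """Alternating rest/task layout of one mental-arithmetic session.

    The schedule is rest-led and rest-terminated: 6 rest epochs bracketing
    5 task epochs, so every task has a rest period immediately before and
    after it.
    """

    variant: Literal["moderate", "simple"]
    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        eps = self.epochs
        if len(eps) != 11:
            raise ValidationError(f"schedule must have 11 epochs, got {len(eps)}")
        if eps[0].kind != "rest" or eps[-1].kind != "rest":
            raise ValidationError("schedule must start and end with a rest epoch")
        for a, b in zip(eps, eps[1:]):
            if a.kind == b.kind:
                raise ValidationError("epoch kinds must strictly alternate")
            if not math.isclose(a.end_s, b.start_s, abs_tol=1e-9):
                raise ValidationError("epochs must be contiguous and non-overlapping")

    @property
    def task_epochs(self) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.kind == "task")

    @property
    def rest_epochs(self) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.kind == "rest")

    @property
    def total_span_s(self) -> float:
        return self.epochs[-1].end_s - self.epochs[0].start_s


def build_schedule(
    variant: str = "moderate",
    task_duration_s: float | None = None,
    rest_duration_s: float | None = None,
) -> ParadigmSchedule:
    """Construct the paradigm schedule for one task-difficulty variant.

    Parameters
    ----------
    variant
        ``"moderate"`` (2x2-digit problems, 30 s epochs) or ``"simple"``
        (1x2-digit problems, 15 s epochs).
    task_duration_s, rest_duration_s
        Override the variant's default epoch durations (seconds, > 0).

    Returns
    -------
    ParadigmSchedule
        Rest-led alternating layout covering ``5*task + 6*rest`` seconds,
        with the variant's printed problems as task labels in order.
    """
    if variant not in VARIANT_DURATIONS:
        raise ConfigurationError(
            f"unknown paradigm variant {variant!r}; expected 'moderate' or 'simple'"
        )
    default_task, default_rest = VARIANT_DURATIONS[variant]
    task_d = default_task if task_duration_s is None else float(task_duration_s)
    rest_d = default_rest if rest_duration_s is None else float(rest_duration_s)
    if task_d <= 0 or rest_d <= 0:
        raise ConfigurationError("epoch durations must be positive")

    problems = MODERATE_PROBLEMS if variant == "moderate" else SIMPLE_PROBLEMS
    epochs: list[Epoch] = []
    t = 0.0
    for i in range(5):
        epochs.append(Epoch("rest", i + 1, t, t + rest_d))
        t += rest_d
        epochs.append(Epoch("task", i + 1, t, t + task_d, label=problems[i]))
        t += task_d
    epochs.append(Epoch("rest", 6, t, t + rest_d))
    return ParadigmSchedule(variant=variant, epochs=tuple(epochs))


def _format_float(x: float) -> str:
    return repr(float(x))


def write_recording(recording: PupilRecording, path: str | Path) -> None:
    """Write a recording in the package CSV dialect (lossless round trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for s in recording.samples:
            diameter = NA_SENTINEL if math.isnan(s.diameter_mm) else _format_float(s.diameter_mm)
            writer.writerow([_format_float(s.time_s), diameter, int(s.valid)])


def read_recording(
    path: str | Path,
    subject_id: str | None = None,
    eye: Literal["left", "right"] = "right",
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> PupilRecording:
    """Read a recording CSV; ``subject_id`` defaults to the file stem.

    Rows with the ``NA`` diameter sentinel become invalid samples.  Raises
    :class:`FormatError` naming the offending line for a bad header,
    non-monotone timestamps or unparsable numbers.
    """
    path = Path(path)
    samples: list[PupilSample] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected header line") from None
        if tuple(h.strip() for h in header) != CSV_HEADER:
            raise FormatError(
                f"{path}:1: malformed header {header!r}, expected {','.join(CSV_HEADER)}"
            )
        prev_t = -math.inf
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            t_str, d_str, v_str = (f.strip() for f in row)
            try:
                t = float(t_str)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unparsable time {t_str!r}") from None
            if t <= prev_t:
                raise FormatError(
                    f"{path}:{lineno}: non-monotone time {t_str} (previous {prev_t})"
                )
            prev_t = t
            if d_str == NA_SENTINEL:
                d, valid = math.nan, False
            else:
                try:
                    d = float(d_str)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: unparsable diameter {d_str!r}"
                    ) from None
                try:
                    valid = bool(int(v_str))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: unparsable validity flag {v_str!r}"
                    ) from None
            samples.append(PupilSample(time_s=t, diameter_mm=d, valid=valid))
    return PupilRecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        samples=tuple(samples),
        eye=eye,
        sampling_rate_hz=sampling_rate_hz,
    )
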
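"""Seeded synthetic pupil recordings with known ground truth.

The generator produces single-eye diameter traces with the morphology of
real task-evoked recordings: a slowly wandering baseline, a first-order
task-locked dilation, additive Gaussian noise and blink/eye-movement
dropouts.  The diameter at sample time t is

    d(t) = baseline + drift(t) + a * r(t) + eps(t)

where drift(t) is a sinusoid of configurable amplitude and period, a is the
subject's dilation amplitude (0 for non-responders), eps is i.i.d. Gaussian
noise, and the dilation kernel r(t) relaxes exponentially toward 1 inside
task epochs and toward 0 inside rest epochs with time constant tau_s.
Blinks are a seeded Poisson point process; each event marks a contiguous
run of samples invalid (dropout mode, diameters replaced by NaN as a device
would report) or pulls them toward a near-closed diameter (spike mode, for
stress-testing artifact flagging).

All randomness flows from a single integer seed.  Cohorts derive the
per-subject seeds from the master seed with ``numpy.random.SeedSequence``
spawning (child i of the master sequence drives subject i), so extending a
cohort never reshuffles existing subjects.

``operating_characteristics`` closes the loop: it simulates cohorts, runs
the full detection pipeline on every recording and reports per-task and
subject-level false-positive rates and subject-level power with Monte Carlo
standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .epoch_stats import analyze_recording
from .errors import ValidationError
from .recording import (
    DEFAULT_SAMPLING_RATE_HZ,
    ParadigmSchedule,
    PupilRecording,
    PupilSample,
    build_schedule,
)


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one synthetic recording.

    Defaults emulate a cooperative adult measured in dim light: resting
    diameter 4.5 mm, task-evoked dilation 0.5 mm with a 2 s time constant,
    0.1 mm slow baseline wander over a minute, 0.05 mm sample noise and a
    physiological blink rate.
    """

    baseline_mm: float = 4.5
    dilation_amplitude_mm: float = 0.5
    tau_s: float = 2.0
    drift_amplitude_mm: float = 0.1
    drift_period_s: float = 60.0
    noise_sd_mm: float = 0.05
    blink_rate_per_min: float = 4.0
    blink_duration_s: float = 0.2
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    blink_mode: Literal["dropout", "spike"] = "dropout"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 < self.baseline_mm < 9.0):
            raise ValidationError(f"baseline_mm must be in (1, 9), got {self.baseline_mm}")
        if self.tau_s <= 0:
            raise ValidationError("tau_s must be positive")
        for name in (
            "dilation_amplitude_mm",
            "drift_amplitude_mm",
            "noise_sd_mm",
            "blink_rate_per_min",
            "blink_duration_s",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.blink_mode not in ("dropout", "spike"):
            raise ValidationError(f"unknown blink_mode {self.blink_mode!r}")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of subjects sharing a parameter template.

    Each subject is a responder with probability ``responder_fraction``;
    responders dilate by ``amplitude_mm``, non-responders by 0.
    """

    n_subjects: int = 20
    responder_fraction: float = 0.7
    amplitude_mm: float = 0.5
    params: SimulationParams = SimulationParams()
    variant: Literal["moderate", "simple"] = "moderate"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValidationError("responder_fraction must be in [0, 1]")
        if self.amplitude_mm < 0:
            raise ValidationError("amplitude_mm must be >= 0")


def _dilation_kernel(times: np.ndarray, schedule: ParadigmSchedule, tau_s: float) -> np.ndarray:
    """First-order relaxation toward 1 in task epochs, 0 in rest epochs."""
    target = np.zeros_like(times)
    for e in schedule.task_epochs:
        target[(times >= e.start_s) & (times < e.end_s)] = 1.0
    r = np.empty_like(times)
    r[0] = 0.0
    if times.size > 1:
        decay = np.exp(-np.diff(times) / tau_s)
        for i in range(1, times.size):
            r[i] = target[i] + (r[i - 1] - target[i]) * decay[i - 1]
    return r


def simulate_recording(
    schedule: ParadigmSchedule,
    params: SimulationParams,
    subject_id: str = "sim",
) -> tuple[PupilRecording, bool]:
    """Simulate one recording over the schedule span.

    Returns the recording and the ground-truth responder label
    (``dilation_amplitude_mm > 0``).  Identical parameters (including the
    seed) produce a bit-identical recording.
    """
    if not schedule.epochs:
        raise ValidationError("schedule has no epochs")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    dt = 1.0 / params.sampling_rate_hz
    n = int(round(schedule.total_span_s * params.sampling_rate_hz))
    times = np.arange(n) * dt

    r = _dilation_kernel(times, schedule, params.tau_s)
    drift = params.drift_amplitude_mm * np.sin(
        2.0 * math.pi * times / params.drift_period_s
    )
    noise = rng.normal(0.0, params.noise_sd_mm, size=n) if params.noise_sd_mm > 0 else np.zeros(n)
    diam = params.baseline_mm + drift + params.dilation_amplitude_mm * r + noise

    # Blink point process: Poisson count over the span, uniform onsets.
    valid = np.ones(n, dtype=bool)
    expected = params.blink_rate_per_min * schedule.total_span_s / 60.0
    n_blinks = int(rng.poisson(expected)) if expected > 0 else 0
    onsets = np.sort(rng.uniform(0.0, schedule.total_span_s, size=n_blinks))
    for t0 in onsets:
        mask = (times >= t0) & (times < t0 + params.blink_duration_s)
        if params.blink_mode == "dropout":
            valid[mask] = False
        else:  # spike: lid closure drags the apparent diameter down
            diam[mask] = np.maximum(0.5, diam[mask] - 3.0)

    diam = np.clip(diam, 0.1, 10.0)
    samples = tuple(
        PupilSample(
            time_s=float(t),
            diameter_mm=float(d) if v else float("nan"),
            valid=bool(v),
        )
        for t, d, v in zip(times, diam, valid)
    )
    recording = PupilRecording(
        subject_id=subject_id,
        samples=samples,
        eye="right",
        sampling_rate_hz=params.sampling_rate_hz,
    )
    return recording, params.dilation_amplitude_mm > 0


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Deterministic per-subject seeds: child i+1 of the master SeedSequence.

    Child 0 is reserved for the responder-label stream, so subject i always
    receives the same seed regardless of cohort size.
    """
    children = np.random.SeedSequence(master_seed).spawn(n_subjects + 1)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children[1:]]


def simulate_cohort(
    spec: CohortSpec,
) -> list[tuple[PupilRecording, bool]]:
    """Simulate a cohort; responder labels and seeds derive from the master seed.

    Responder labels are drawn from a dedicated label stream (child 0 of the
    master seed sequence); subject i's recording uses the seed derived from
    child i+1, so cohorts are reproducible and extensible without
    reshuffling existing subjects.
    """
    master = np.random.SeedSequence(spec.params.seed)
    label_rng = np.random.default_rng(master.spawn(1)[0])
    labels = label_rng.random(spec.n_subjects) < spec.responder_fraction
    seeds = subject_seeds(spec.params.seed, spec.n_subjects)
    schedule = build_schedule(spec.variant)
    out: list[tuple[PupilRecording, bool]] = []
    for i in range(spec.n_subjects):
        amp = spec.amplitude_mm if labels[i] else 0.0
        p = replace(spec.params, dilation_amplitude_mm=amp, seed=seeds[i])
        rec, truth = simulate_recording(schedule, p, subject_id=f"sim{i:04d}")
        out.append((rec, truth))
    return out


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte Carlo operating characteristics of the detection pipeline."""

    n_subjects: int
    n_null: int
    n_responders: int
    task_fp_rate: float
    task_fp_se: float
    subject_fp_rate: float
    subject_fp_se: float
    power: float
    power_se: float


def _rate_and_se(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return float("nan"), float("nan")
    p = k / n
    return p, math.sqrt(p * (1.0 - p) / n)


def operating_characteristics(
    spec: CohortSpec,
    n_reps: int = 1,
    alpha: float = 0.01,
    m: int = 5,
    k: int = 4,
) -> OperatingCharacteristics:
    """Estimate false-positive rates and power by full-pipeline simulation.

    Runs ``n_reps`` independent cohorts (replicate r reuses the spec with
    master seed ``spec.params.seed + r``), analyses every recording with the
    standard pipeline and tallies, among truth-negative subjects, the
    per-task significant-dilation rate and the subject-level
    command-following rate (false positives), and among truth-positive
    subjects the detection rate (power).
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    schedule = build_schedule(spec.variant)
    n_null = n_resp = 0
    task_fp = subj_fp = detected = 0
    for rep in range(n_reps):
        rep_spec = replace(spec, params=replace(spec.params, seed=spec.params.seed + rep))
        for rec, truth in simulate_cohort(rep_spec):
            result = analyze_recording(
                rec, schedule, alpha=alpha, m=m, k=k
            )
            if truth:
                n_resp += 1
                detected += result.command_following
            else:
                n_null += 1
                task_fp += result.n_significant
                subj_fp += result.command_following
    task_rate, task_se = _rate_and_se(task_fp, 5 * n_null)
    subj_rate, subj_se = _rate_and_se(subj_fp, n_null)
    power, power_se = _rate_and_se(detected, n_resp)
    return OperatingCharacteristics(
        n_subjects=n_null + n_resp,
        n_null=n_null,
        n_responders=n_resp,
        task_fp_rate=task_rate,
        task_fp_se=task_se,
        subject_fp_rate=subj_rate,
        subject_fp_se=subj_se,
        power=power,
        power_se=power_se,
    )
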
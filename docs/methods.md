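# Methods

## The paradigm and its statistical model

A session consists of five mental-arithmetic task epochs alternating with
six rest epochs, rest-led and rest-terminated, so that every task has a
rest period immediately before and after it. Two difficulty variants are
built in: *moderate* (2×2-digit products, 30 s task and rest epochs,
330 s total) and *simple* (1×2-digit products, 15 s epochs, 165 s total).
Epoch intervals are half-open `[start, end)`; a sample exactly on a
boundary belongs to the later epoch, so the epochs partition the session
without gaps or double counting.

The recording is a single-eye pupil-diameter trace in millimetres. The
nominal sampling rate defaults to 30 Hz (handheld infrared pupillometers
report in this range; the value is configurable and only affects synthetic
data and plausibility checks, not the statistics, which operate on whatever
samples are present).

### Per-task test

Each task epoch is compared with its two flanking rests. The default test
is the two-sample rank-sum (Mann–Whitney) test of the task samples against
the two rest epochs pooled into one vector. A published description of
this comparison may name the *Wilcoxon signed-rank* test, but signed-rank
requires paired observations of equal length, which task/rest epochs do not
provide; the rank-sum test is the natural unpaired analogue and is the
default here. A `signed_rank_truncated` mode is available for
sensitivity analyses: both vectors are trimmed symmetrically to the shorter
length (excess split between the ends, one more from the tail when odd),
paired positionally, and tested with the signed-rank statistic.

Exact null distributions are used where feasible: for the rank-sum test
when the smaller group has ≤ 8 observations and there are no ties, and for
the signed-rank test when ≤ 12 non-zero differences remain without tied
magnitudes. Otherwise the tie-corrected normal approximation is used,
without continuity correction (configurable in principle via the underlying
scipy routines; the default is documented so results are reproducible).
Degenerate inputs are resolved by convention: all-tied rank-sum inputs and
all-zero signed-rank differences give p = 1 with a `degenerate` flag.

### Decision rule

A task is a *significant dilation* when (a) the task median exceeds the
pooled-rest median and (b) the Bonferroni-adjusted p-value
`p_adj = min(1, m·p_raw)` with m = 5 is below α = 0.01. The adjusted-scale
reading of the threshold (equivalently raw p < 0.002) was chosen over the
raw-scale reading because it is the stricter and more standard
interpretation of "significance followed by Bonferroni correction"; both α
and m are exposed. The default p-value is two-sided and the dilation
direction is enforced separately through the median comparison; a
one-sided `greater` mode is available and roughly halves p for true
dilations. Rest pooling defaults to a single pooled comparison per task;
a `both` mode instead requires the task to beat each flanking rest
separately and carries the larger (least favourable) p-value.

A subject shows *command following* when at least k = 4 of the 5 tasks are
significant dilations.

Samples within an epoch are treated as independent observations. Real
pupil traces are autocorrelated, so the per-task p-values are
anticonservative as statements about the physiological process; the
decision rule inherits the calibration of the published procedure rather
than correcting it. No baseline normalisation is applied — diameters are
analysed in raw millimetres — and no artifact removal is performed by
default. An optional artifact flagger (minimum-diameter and maximum-step
rules) marks samples invalid without altering diameters and is OFF unless
explicitly enabled.

### Group comparison

Success proportions are aggregated per group as the distribution of
subjects over 0..5 significant dilations. Two groups are compared with the
risk ratio using the Wald method on the log scale:
`se_log = sqrt(1/s1 - 1/n1 + 1/s2 - 1/n2)`,
`CI = exp(log RR ∓ z_conf · se_log)`, `z = log RR / se_log`, two-sided p
from the standard normal. No continuity correction or exact interval is
implemented, so both groups must have at least one success. Reported
roundings: integer percent for table-style proportions, one decimal for
narrative proportions, two decimals for RR/z/CI.

## Quality control

Participants are screened before analysis on the Neurological Pupil index
(NPi), a proprietary 0–5 light-reflex summary score consumed here as a
given number: inclusion requires NPi ≥ 3 in **both** eyes and an absolute
inter-eye difference strictly below 0.7 (a difference of exactly 0.7
excludes; the rule is symmetric in the eyes). Every violated rule is
reported, not just the first. Recordings are additionally inspected
visually via run charts — diameter against time with green task / yellow
rest shading and no interpolation across dropouts.

## Synthetic recordings

The generator is the minimal structure that reproduces the morphology of
real task-evoked recordings; it is a fixture factory, not a fitted model.
The diameter at time t is

    d(t) = baseline + drift(t) + a · r(t) + ε(t)

with a sinusoidal baseline wander `drift`, i.i.d. Gaussian noise ε, and a
dilation kernel r(t) that relaxes exponentially toward 1 inside task
epochs and toward 0 inside rest epochs with time constant τ. Blinks are a
Poisson point process; each event marks a contiguous run of samples
invalid (dropout mode, diameter reported as `NA`, the device-like default)
or pulls the apparent diameter down (spike mode, for stress-testing the
artifact flagger).

Defaults describe a cooperative adult in dim light: baseline 4.5 mm,
dilation amplitude a = 0.5 mm (a robust but physiologically plausible
task-evoked change), τ = 2 s, drift 0.1 mm over a 60 s period, noise SD
0.05 mm, 4 blinks/min of 0.2 s, 30 Hz sampling. Cohorts draw responder
labels with a configurable fraction; per-subject seeds derive from the
master seed via `numpy.random.SeedSequence` spawning (child 0 feeds the
label stream, child i+1 subject i), so a cohort can be extended without
reshuffling existing subjects and identical seeds give bit-identical
recordings.

What the generator does **not** emulate: luminance responses, light-reflex
dynamics, autocorrelated physiological noise, inter-subject variability in
baseline or amplitude, or non-stationary attention. Passing tests on
synthetic cohorts therefore demonstrate that the pipeline implements its
stated procedure and is well calibrated under exchangeable noise — not
that the procedure has any particular sensitivity or specificity on real
patients.

## Operating characteristics

`operating_characteristics` runs the full pipeline over simulated cohorts
and reports the per-task false-positive rate and subject-level
false-positive rate among truth-negative subjects, and the detection rate
(power) among responders, each with binomial Monte Carlo standard errors.
Null-calibration runs use zero drift: the sinusoidal wander makes epochs
non-exchangeable (a trend shifts medians between adjacent epochs) and so
inflates the per-task rate — by design, that configuration probes the
documented anticonservatism rather than the nominal level. Under
independent noise the per-task rate is bounded by the raw-scale level
(0.002 for α = 0.01, m = 5; halved again in practice by the direction
requirement), and the subject-level rate by the Bin(5, p_task) tail
P(X ≥ 4), which is ~8·10⁻¹¹ — the decision rule is extremely specific
under the null.

Problem sizes used by the validation suite and the acceptance script — 500
null subjects for calibration, 200 responders for power, exhaustive
enumeration oracles up to group size 8 (rank-sum) and 12 (signed-rank) —
were chosen to give Monte Carlo standard errors small relative to the
quantities checked while keeping a full run fast on one CPU.

## Known limitations

* Per-sample testing ignores autocorrelation; p-values quantify evidence
  under an exchangeability assumption that real traces violate.
* The Wald risk-ratio interval is a large-sample method; zero-success
  groups are rejected rather than corrected.
* The NPi is consumed, never computed; device export formats are not
  parsed — recordings enter through the open CSV dialect documented in
  `pupilcf.recording`.
* The paradigm decides *command following*, not consciousness; clinical
  interpretation is out of scope.
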
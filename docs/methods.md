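# Methods

This package re-implements, as reusable and tested code, the analysis
chain of reward-modulated feedback-control experiments: five reaching
tasks in which human participants counter mechanical perturbations or
visual cursor/target jumps, with surface EMG from five upper-limb muscles
recorded at 1000 Hz, half of the trials offering a monetary return.  The
pipeline quantifies, per participant, (i) when a feedback response begins
(divergence latency), (ii) how large it is (feedback gain) and whether
reward scales it (the log-ratio G), and (iii) behavioral performance
(movement times, reaction times), with paired nonparametric statistics
across participants.

## Task designs and schedules

Each task is a small factorial design (`rewardemg/designs/*.yaml`):

| task | factors | epoch | total |
|---|---|---|---|
| in_out | perturbation × target × reward | 16 | 336 (3 blocks) |
| target_selection | targets × perturbation × reward | 16 | 224 (2 blocks) |
| cursor_jump / target_jump | jump(3) × reward | 12 | 312 |
| proprio_rt | reward | 4 | 108 |

Every epoch contains each factor combination exactly twice and is
shuffled independently; `make_schedule(design, seed)` is a pure function
of its arguments (numpy `default_rng(seed)`, epochs consumed
sequentially).

Monetary returns use two forms.  Time-in-target (In-Out task):
`g·exp(−τp)` with `p = 1 − min((x − x0)/(xf − x0), 1)`, `g = 15` ¢,
`x0 = 500` ms, `xf = 800` ms and condition-specific τ.  Movement-time
form (all other tasks): `max(g·(scaler·exp(−τ·MT/MTmax) + shifter), 0)`
with the per-condition calibration table shipped in the YAML files.  Two
readings of the printed MT formula are possible (shifter inside or
outside the factor of `g`); we place it inside because scaler and shifter
are commensurate dimensionless calibration constants, and note that the
Reaction-Time parameters (scaler = 1, shifter = 0) give the same maximum
either way.  `x` for the In-Out return is the *accumulated* (not
necessarily contiguous) time inside the target between perturbation onset
and trial end.  The printed formula yields a positive return for every
`x`, including below `x0`; it is followed as printed.

Movement time is task-specific: perturbation onset → target entry
(regardless of speed) for the proprioceptive tasks, or start-position
exit → first sample inside the target with radial speed < 10 cm/s for the
visual tasks, with radial velocity from centered finite differences of
radial position.  Trials that never satisfy the criterion return NaN and
are excluded downstream.

## Synthetic data generator

The generator exists so that every estimator can be validated against
known ground truth without any recordings.  Raw EMG per muscle is

    raw(t) = carrier(t) · E(t) + noise_sd · white(t)

with a unit-variance Gaussian carrier band-limited to 30–220 Hz, so the
analysis chain (band-pass, rectify, normalize) has expectation
proportional to the envelope E(t).  E(t) is a tonic baseline (1.0
normalized units, sustained against the background load) plus
condition-dependent evoked components, each a half-Gaussian rise
(σ = 10 ms) to a 150 ms plateau followed by exponential decay
(τ = 150 ms), starting exactly at the alignment event plus the
ground-truth latency (25 ms short-latency, 50 ms long-latency, 100 ms
target selection, 120 ms visuomotor, by default).  Mechanical responses
are additionally delayed by the 4 ms actuation lag that the analysis
correction compensates.  Rewarded trials multiply every evoked amplitude
by `reward_gain_factor` (ground-truth e^G, default 1.25); trial-to-trial
variability is a shared log-normal factor (σ = 0.2), participants get
log-normal amplitude factors (σ = 0.15) and Gaussian MT offsets
(σ = 40 ms).

Evoked amplitudes are chosen from the ROC algebra of the signal model:
for rectified Gaussian carriers the per-sample AUC between envelope
levels e_a > e_b is `1 − (2/π)·arctan(e_b/e_a)`, so the sustained 75 %
criterion requires an envelope ratio above ~2.4.  Defaults (e.g.
short-latency 6.0 vs 0.15 baseline units; long-latency +14.0 excitatory
vs −5.0/−6.5 inhibitory, the goal-dependent component being inhibitory on
the side moving with the perturbation) give plateau ratios of 3–9, i.e.
responses several times the tonic level, consistent with stretch
responses of a pre-loaded extensor.  No published signal-to-noise figures
exist for these recordings, so these levels are chosen once to put the
estimators in their working regime; they emulate the *structure* of the
recordings, not their exact SNR.  The voluntary burst of the
reaction-time task uses a faster rise (σ = 1.5 ms) and larger amplitude
(40× tonic), reflecting ballistic movement-onset EMG; its onset is the
per-trial reaction time, drawn with means 147.0 ms (no reward) and
134.6 ms (reward) — the published group medians — and σ = 25 ms.

Kinematics are minimum-jerk radial profiles whose duration is solved
(analytically for threshold entry, by root-finding for the velocity
criterion) so the task's own MT definition recovers the drawn
ground-truth MT exactly up to the 1 ms grid.  Rewarded movement times are
shortened by `reward_mt_shift_ms` (default 25 ms) before solving.
Simplifications relative to real data: movement starts at the
perturbation (no separate voluntary-onset delay outside the RT task), no
joint-space dynamics, no EMG–kinematics coupling, no electrode artifacts,
stationary baseline.  Passing tests therefore demonstrate correctness of
the estimators under the stated signal model, not robustness to every
property of real recordings.

Calibration data are four 2 s static holds at the tonic envelope.
Randomness: one dataset seed expands to per-trial generators keyed
`(seed, participant, trial)` via numpy SeedSequence, so any subset is
reproducible in isolation.

## Preprocessing

Band-pass 20–250 Hz → full-wave rectification → division by the
per-muscle normalization scalar (mean of the band-passed rectified hold
signal from 250 ms after entry to 250 ms before the end of each 2 s hold,
concatenated over the four holds: 6000 samples at 1000 Hz).  The filter
is a 4th-order Butterworth applied forward–backward (scipy `sosfiltfilt`
with its default odd-reflection padding): the filter order and phase
behavior are not dictated by the analysis definition, and zero phase is
essential because any group delay would bias every latency estimate.  The
first/last 50 ms of a series are treated as transient and never enter
analysis windows.  Alignment shifts the time base so the event is t = 0,
adding the 4 ms actuation correction for mechanical perturbations only.
Trial-baseline statistics use the half-open window [−350, −300) ms before
the anchoring event (displacement onset, or target appearance in the jump
tasks), exactly 50 samples; the SD is the within-trial across-sample SD
of that window — the criterion speaks of the *trial* baseline, which
supports the within-trial reading.

## Divergence latency

Per sample of the analysis window ([−100, +300] ms around the alignment
event), the ROC AUC between the two contrasted trial sets is the
Mann–Whitney probability (midranks; ties count ½), using all trials
without averaging, per participant and reward condition.  The threshold
is reached at the first index where two consecutive samples fall beyond
the symmetric 25–75 % band (either direction).  A two-segment linear
regression is then fitted to the AUC from the fit start (t = 0 for
mechanical contrasts, window start for visual ones) up to the crossing:
every breakpoint is searched exhaustively (1 ms resolution, minimum 3
samples per segment, two independent lines, the breakpoint sample shared)
and the SSE-minimizing breakpoint — ties broken toward the earliest,
conservative, time — is the latency.  Because the AUC is rank-based the
estimate is invariant to any strictly monotone amplitude transform.
Trials in which the goal target lies in the perturbation direction are
included in the short-latency contrast.  Absence of a sustained crossing
is a value (invalid estimate), not an error: channels without evoked
differences genuinely have no measurable divergence.

## Feedback gains, reaction times

The gain window starts at each participant's own latency for that reward
condition (25 ms wide for the short-latency response to avoid overlap
with the long-latency one, 50 ms otherwise); the gain is the absolute
difference of the trapezoid-rule integrals of the two conditions' mean
traces over that window (units: normalized EMG × ms; only ratios are
interpreted).  Anchoring at the per-condition latency avoids the
fixed-window confound in which a latency shift masquerades as a gain
change; the price is that latency-estimate noise propagates into G, which
dominates the spread of per-participant G estimates in simulation.
G = ln(gain_rewarded / gain_non-rewarded); non-positive gains (possible
in null data) make G undefined and are excluded pairwise with a logged
count.  In the RT task there is no condition contrast: the integral of
the trial's own trace from its reaction time over 50 ms is averaged per
participant and reward.  Reaction time is the first t ≥ 0 at which the
processed triceps trace exceeds (strictly) baseline mean + 3 SD for 5
consecutive samples; trials never meeting the criterion are discarded.
The anticipatory control (fixed-delay task only) compares mean triceps
EMG in [−20, 0) ms before the perturbation between contrasted conditions.

## Statistics

Wilcoxon signed-rank on paired participant summaries: zero differences
dropped, midranks for ties (half-integer W possible), W = sum of positive
ranks, effect size r = W / (n(n+1)/2) — the proportion of favorable
ranks, which reproduces the published (W, n, r) triples exactly at two
decimals.  Two-sided p-values are exact for n ≤ 25, computed by
convolving the null distribution over the signed ranks (identical to
enumerating all 2^n sign assignments); larger n uses the normal
approximation with tie and continuity corrections.  No multiple-testing
correction is applied (per-muscle tests are reported raw).

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to make the stated tolerances
meaningful at desk scale: latency recovery uses 100 seeded replicates at
50 trials/side; gain recovery pools 48 synthetic participants (three
seeded datasets of 16) at 50 trials/side per reward condition; the null
calibration runs 100 replicate datasets of 16 participants with 3 epochs
(48 trials) each.  Unless stated otherwise simulations use the triceps
channel only, since all analysed contrasts are defined on it.  Breakpoint
SSE ties break to the earliest candidate; the RT threshold is strict;
baseline windows are half-open; integrals use the trapezoid rule on the
1 ms grid.

## Known limitations

- The generator's SNR is a modeling choice (see above); absolute gain
  values are not comparable to any real recording.
- Per-participant G inherits latency-estimation noise by design (shared
  with the original analysis); group medians, not individual values, are
  the meaningful quantity.
- The exact pre-crossing fit-window extent of the original analysis is
  not published; it is exposed as `fit_start_ms` with the defaults above.
- Group-level results that depend on the human recordings are out of
  scope; the pipeline's external entry point is the documented
  manifest + time-series text layout.
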
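# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `vnspupil`. It describes what the code computes; every
empirical number cited here is produced by the test suite or
`scripts/acceptance.py`.

## Data model and binning

All times are seconds. Trials are rows of a plain DataFrame (documented schema
in `vnspupil.core.TRIAL_COLUMNS`); pupil, spikes and licks live in small
validated dataclasses. After alignment to sound onset, bins are half-open
`[start, start + width)` with widths restricted to 20–33.3 ms (30–50 Hz). The
default is 50 Hz (20 ms), the finer end of the allowed range, which makes the
epoch boundaries at 60 ms and 1 s land exactly on bin edges; other epoch edges
are snapped to the nearest bin edge and the snap is logged.

Pupil is linearly interpolated to bin centres and shifted by the **pupil lag**
(default 0.75 s): the pupil value assigned to the spike bin at time *t* is the
trace at *t − lag*, i.e. pupil leads spikes, reflecting the lagged relationship
between pupil diameter and auditory-cortical excitability. Trials whose pupil
queries fall outside the recorded trace are excluded (never zero-filled, which
would bias the pupil regressors) and logged.

## Blink removal

Blinks are transient artifacts in the fitted pupil diameter. Detection uses
the first difference of the trace: samples whose derivative lies more than 6 SD
from the mean derivative are flagged. The mean and SD are **re-estimated
excluding flagged samples until a fixed point** (monotone, hence convergent).
A one-shot global SD is inflated by the blinks themselves, which misses long,
slow blinks and makes the operation non-idempotent; with the robust estimate,
detection of injected blinks is essentially complete, artifact-free traces
produce no spurious intervals, and a second pass is a no-op (all verified on
synthetic traces in the suite).

Flagged events showing a decrease below the pre-event level followed by
recovery are blinks; monotone jumps are tracking glitches — both are excised
(counted separately). A 6-s window **centred** on each event (the centring is a
package choice; overlapping windows merge) is removed and bridged by linear
interpolation between the nearest surviving samples; boundary events hold the
nearest surviving value. Untouched samples are bit-identical. A trace with no
surviving samples raises an error.

## Behavioural learning (ΔR)

A trial counts as a response when at least one lick falls in the half-open
window [onset + 0.2 s, offset + 0.15 s). ΔR = R_T1 − R_T2 is computed over
**blocks of 20 consecutive target (T1/T2) trials** — reference/distractor
trials are skipped entirely — with per-label response fractions inside each
block. With ~1:1 interleaving this coincides with per-label decades of 10
trials; mixed 20-trial blocks were chosen because they are well defined for
any interleaving. A final partial block is kept only with ≥ 3 trials of each
type; a full block missing one type yields NaN and a flag.

Switch/no-switch difficulty is derived from the trial table itself: a 2-day
condition is a "switch" when the relative frequency order of T1 vs T2 reversed
relative to the previous condition (requires the optional `t1_freq_hz` /
`t2_freq_hz` columns; otherwise "unknown"; the first condition is
"no_switch"). Cell summaries use classical two-sided one-sample t tests of
mean ΔR against 0 and two-sample t tests between VNS conditions; cells with
fewer than two blocks are omitted (no SEM exists). Degenerate all-constant
cells report t = 0, p = 1 (zero mean) rather than NaN.

## Evoked responses and plasticity testing

PSTH = trial-averaged rate aligned to tone onset; evoked rate subtracts the
mean spontaneous rate over the 0.5 s before onset. Epochs (onset 0–60 ms,
sustained 60–1000 ms, offset 0–100 ms after tone offset) are
spontaneous-subtracted **per trial**, making every epoch measure invariant to
additive rate shifts.

The plasticity endpoint is the sustained epoch (onset/offset responses are
computed but not tested by default). Per unit, pre-vs-post sustained responses
are compared with a two-sided Wilcoxon rank-sum (Mann–Whitney) test — exact
null distribution for small tie-free samples, midrank/tie-corrected normal
approximation otherwise; two identical constant samples return p = 1 by
convention. A Bonferroni option (default ×2) serves the repeated 20+20-trial
pairing design. Units with |mean sustained| < 1 spk/s in every phase are
excluded as non-responsive (the threshold is a package choice; no principled
value exists). Population direction among significant units uses the Wilcoxon
sign-rank test on unit mean differences.

## Pupil regression (arousal decomposition)

Per unit, the trial × bin rate matrix r(i,t) is modelled as

    r_pupil(i,t) = b0 + b1·r̄(t) + b2·p(i,t) + b3·r̄(t)·p(i,t)

with r̄(t) the **trial-averaged PSTH estimated from the training folds only**
(using the per-trial response itself on the right-hand side would make the
regression degenerate — this reading matches "baseline and response gain":
b2 is the pupil effect on baseline rate, b3 on response gain). The pupil is
mean-centred per session, so b0 decouples from b2; coefficients are reported
in centred units. Fitting is ordinary least squares with k-fold (default 20)
cross-validation; folds interleave by trial index (trial i → fold i mod k),
deterministic, with optional seeded shuffling. Held-out predictions assemble
r_pupil; r_persist = r − r_pupil reconstructs r exactly. If the pupil SD falls
below 1% of its mean, the pupil columns are dropped (b2 = b3 = 0) with a
warning; with fewer trials than folds the fold count shrinks to the trial
count (one fold degenerates to fit-and-predict-in-sample).

Pre- and post-VNS blocks are fitted **jointly with shared coefficients**, so
genuine phase differences land in r_persist instead of being absorbed by
phase-specific fits. The pupil-corrected plasticity test then rank-sums
per-trial sustained r_persist pre vs post, exactly mirroring the raw test.
Raw (not baseline-subtracted) rates enter the regression; the intercept and
the b2 term absorb the spontaneous level.

**Known property — conservative null behaviour.** When the pupil differs
systematically between phases (slow drift, session trends), the pupil
regressor partially absorbs *chance* pre/post differences as well, so under a
true null the corrected test rejects below its nominal level (measured ≈ 0.03
at α = 0.05 under the generator's drift; exactly nominal, ≈ 0.05, when pupil
is shuffled across trials). This is inherent to regressing on a
phase-contrasted covariate and is the price of the method's specificity: with
pupil-driven changes only, the corrected false-positive rate stays at α while
the raw analysis inflates several-fold. It depends on the drift's timescale
relative to block length, not its amplitude.

The gating analysis pairs each unit's mean evoked dilation during pairing
trials (fraction change relative to the first 0.8 s of each trial) with its
persistent-change magnitude |Δ sustained r_persist| and reports the Pearson
correlation with its classical two-sided p.

## Synthetic data generator

The generator defines the study conditions; all randomness flows from one
seed (same seed ⇒ bit-identical output), and a `GroundTruth` object records
every injected quantity.

* **Session design**: three blocks (pre/during/post) of 20 presentations per
  tone, 1-s tones, 12-s intertrial interval; VNS in the during block either
  paired (onset 100 or 150 ms before the tone) or unpaired (6 s after tone
  onset). Spikes exist only in pre/post blocks (the amplifier is disconnected
  during stimulation). A single best-frequency tone is the default; an off-BF
  tone can be interleaved.
* **Pupil**: baseline 60 px; AR(1) drift with time constant ≈ 110 s and
  stationary SD 0.15 of baseline; a linear within-block decline of 0.35 and a
  post-block arousal transient of 0.35 decaying over ≈ 200 s (session-scale
  dynamics chosen to match the within-session decline and post-session rebound
  seen in such recordings); gamma-shaped VNS dilation kernels (shape 4, unit
  peak scaled to 10% at a 4.5–7 s latency); blinks at 1/min as 0.2–0.5 s
  V-dips to ~5% of diameter.
* **Spiking**: rate(t) = (1 + g·p_norm(t − lag))·template(t) + b·p_norm(t − lag),
  where the template (spontaneous 10 spk/s + onset 40 / sustained 20 /
  offset 10 spk/s boxes, per-unit lognormal amplitude jitter σ = 0.2) includes
  the spontaneous rate — pupil gain modulates baseline and evoked activity
  alike, which keeps (b2, b3) identifiable as (b, g). p_norm is the fractional
  deviation of the artifact-free pupil from its session mean. Spikes are
  inhomogeneous Poisson on a 1-ms grid within ±(1, 2.5) s of each tone;
  negative instantaneous rates clip at zero with a logged count, and clipping
  beyond 1% of bins is a configuration error. Plastic units multiply the
  sustained *evoked* amplitude by (1 − d) post-VNS (default d = 0.3).
* **Behaviour**: a schedule of 2-day conditions (paired/unpaired × which tone
  is the higher frequency, balanced); 200 target trials plus 50 distractors
  per day. The generative ΔR ramps linearly within each day toward configured
  day-end asymptotes (defaults: paired 0.1 → 0.3, unpaired 0 → 0), scaled by
  0.7 on switch transitions; responses are Bernoulli with p(T1/T2) = base ±
  Δ/2 around a base rate of 0.5, reference trials at 0.15, reward delivery
  independent of responding (classical conditioning). Lick times fall
  uniformly in the response window, plus consummatory licks after reward.

What the generator does **not** emulate: luminance effects, eye position and
saccades, non-Poisson spiking (refractoriness, bursting, adaptation),
correlated noise across units beyond the shared pupil, tuning-curve structure
beyond a single BF flag, and reaction-time structure in licking. Passing tests
therefore demonstrate correctness of the analysis under the stated statistical
assumptions, not robustness to every property of real recordings.

## Problem sizes and numerics

The test suite and acceptance script use desk-scale designs: 100-trial phases
for parameter recovery (200 trials per fit), 10–100 units per simulated
session, 20-seed medians for recovery checks, and 2000 null units for
false-positive calibration. Exact rank-sum enumeration is checked for group
sizes ≤ 8. Float comparisons use 1e-9 tolerances where exactness is the claim
(blink interpolation, decomposition identity) and sampling-based intervals
elsewhere. CSV output uses `%.9g` formatting; round trips are exact to that
precision.

## Limitations

* The cross-animal repeated-measures ANOVA is out of scope: the package emits
  the per-animal/day/condition table and implements paired contrasts only.
* Pipeline inputs start from an extracted pupil diameter trace; video
  processing and spike sorting live upstream.
* The corrected plasticity test's conservative null behaviour under slow
  pupil drift (above) means its significant-unit counts are lower bounds in
  strongly drifting sessions.
* Gating within a single simulated session is degenerate (all units share one
  pupil trace); meaningful gating correlations require units pooled across
  sessions, as the generator's record-level simulator provides.
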
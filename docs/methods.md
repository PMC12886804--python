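# Methods

This note documents the models, defaults and numerical choices behind
`hapticlab`, and what the synthetic cohort does and does not emulate.

## Force rendering (`hapticlab.conditions`)

The belt force law is `F_x = A_x · e_p · (K_c·e_b + K_v·sin(2π f_v t))`
per motor, with the five condition profiles registered verbatim:

| condition | A_a | A_b | K_c (N/mm) | K_v (N) | f_v (Hz) | mode |
|---|---|---|---|---|---|---|
| GC | 1 | −1 | 0.006 | 0 | — | clench |
| GV | 1 | −1 | 0.6 | 1.8 | 60 | clench |
| RC | 0.05 /deg | 0.05 /deg | 0.6 | 0 | — | stretch |
| RV | 0.05 /deg | 0.05 /deg | 0.6 | 1.8 | 60 | stretch |
| NH | 0 | 0 | 0 | 0 | — | none |

Notes and deliberate choices:

* **GC vs GV stiffness.**  The 100× gap between the GC (0.006 N/mm) and
  GV (0.6 N/mm) continuous stiffness is implemented exactly as published
  for the device.  It may be a transcription artifact of the original
  parameter table; both values are exposed through the configuration, and
  nothing in the package depends on their ratio.
* **Full-loosening floor.**  For the clench conditions a negative pose
  error proportionally reduces the clench until the belt is slack; the
  commanded continuous force is floored at 0 N and the vibrotactile term
  is rendered only in the over-closure region.
* **Vibration placement in stretch mode.**  By default the vibrotactile
  term is applied to both co-rotating motors, which keeps the rendered
  force antisymmetric in the pose error (direction reversal flips both
  forces exactly).  `vibration_on="leading"` restricts it to the motor
  pulling in the error direction.
* **Belt setpoint.**  The displacement setpoint is `d_ref = G·e_p` with
  configurable gain (defaults 25 mm per unit grasp error, 0.5 mm/deg),
  preserving the two-level structure (pose-error setpoint + low-level
  impedance loop); the original gain is not published.
* Saturation: ±3.68 N per motor, applied after the law.

## Device model (`hapticlab.device`)

The actuator+belt is a linear underdamped second-order system
`H(s) = g·ω_n² / (s² + 2ζω_n s + ω_n²)` calibrated from the step
response: ζ solves `overshoot = exp(−ζπ/√(1−ζ²))` for the measured 49.4 %
(ζ = 0.2190), ω_n comes from the 81 Hz damped oscillation, and the DC gain
from the 2.14 N steady state at 1.85 V.  The separately measured 158 Hz
cutoff and 74 Hz resonance peak are *not* enforced: a pure second-order
fit to the step response predicts its own frequency response (resonance
at `f_n√(1−2ζ²) ≈ 79 Hz`), and the step response is the self-consistent
subset.

Numerics: simulation uses exact zero-order-hold discretization at the
1 ms control-loop period (matrix exponential, via `scipy` state-space
conversion), so integration error does not contaminate the step metrics.
The trace peak is refined by a local cubic-spline interpolation around
the sampled maximum; without it, the ~1 ms sampling bias leaks into the
overshoot and breaks the damping round-trip property
(`ζ → overshoot → ζ` recovers to better than 1e−4 with the spline).
Rise time is the 0→100 %-of-steady-state crossing, linearly interpolated
(closed form `(π − atan(√(1−ζ²)/ζ))/ω_d` ≈ 3.5 ms for the bench model,
printed as 4 ms at loop resolution); settling uses a 2 % band.  The chirp
experiment drives a 30 s logarithmic sweep (0→250 Hz; log sweeps start at
0.1 Hz) through the discretized model and estimates magnitude with the H1
spectral estimator (cross-spectrum over input auto-spectrum, Welch,
8192-sample segments).

## Synthetic cohort (`hapticlab.cohort`)

No raw recordings of the original experiment are public, so all
downstream stages run on a generated cohort.  The subject model is a
behavioural stand-in, not biomechanics: each degree of freedom (grasp
ratio, pronation angle) tracks a piecewise-constant target through
delayed, underdamped second-order dynamics (exact ZOH discretization at
100 Hz).  At each phase boundary of the pick-pour-return-rest repetition
the target is redrawn as `nominal + offset`:

* unguided (NH, or the DoF a condition does not guide):
  `offset = bias + N(0, σ_NH)` in the biased phases (grasp: grab and
  hold phases; pronation: pouring phase);
* guided: `offset = (1 − salience)·bias + N(0, σ_modality)`.

Defaults (chosen once, from the published condition-level means and
spreads of the original cohort, and then fixed):

| parameter | grasp | pronation | units |
|---|---|---|---|
| reaction delay | 0.3 | 0.3 | s |
| response natural frequency | 0.8 | 1.5 | Hz |
| response damping ζ | 0.35 | 0.35 | — |
| no-haptics bias | +0.2 | +30 | ratio / deg |
| endpoint σ (V, C, NH) | 0.04, 0.08, 0.12 | 3.7, 11.7, 20.6 | ratio / deg |
| salience (V, C) | 1.0, 0.5 | 1.0, 0.75 | — |
| tremor SD | 0.01 | 1.0 | ratio / deg |

The pronation σ values are the published phase-3 across-subject SDs; the
grasp σ values sit at or below the published spreads because those
include between-subject differences the generator does not model (see
Limitations).  Task reference: grasp ratio 0.5, pouring angle 60°, phase
durations (2, 3, 3, 2, 5) s with the 5 s rest fixed by the protocol;
5 repetitions per trial, 2 trials per condition, 9 subjects.  These
dynamics make the cohort-median |error| transient settle inside 10 % of
the reference in ≈1.2 s (GV) and ≈0.8 s (RV) — within the 2.5 s / 1.2 s
observed for the vibrotactile conditions — while the continuous-only
conditions approach but do not enter the band, and NH retains its bias.

**Kinematics** (240 Hz): segments follow per-phase minimum-jerk transport
(peak speed `1.875·d/T`) with band-limited additive tracking noise
(2 mm position, 0.5° angle); the wrist angle resamples the pronation
trace.  Velocities are forward differences of positions (and
accelerations of velocities), so the rectangle-rule integral of velocity
equals the net displacement exactly — a property the tests rely on.

**EMG** (2148.1 Hz, 13 muscles: BIC, TRI, BRACH, PRON, SUP, FD, ED, AP,
DELT A/M/P, INFRAS, PECT): envelopes are `W_true·H(t)` from a fixed
3-synergy basis (hand-grasp, arm-transport, pronosupination columns) with
phase-keyed activation levels and 0.3 s cosine ramps, plus Gaussian noise
at 5 % of the signal RMS, clipped at zero.  The raw signal multiplies the
envelope by a 30–450 Hz band-limited Gaussian carrier normalized to unit
mean absolute value, so the analysis chain's rectified mean recovers the
envelope scale after MVC division.  Artifacts are 5 ms spikes at 0.2 /s
with amplitude 0.5–1.5 × MVC (roughly 30× the task-level signal — clearly
abnormal, but of a magnitude a median stage can reject).  Spikes are kept
0.5 s clear of the record edges: real recordings start before the task
and the settling margin is trimmed during synchronization, whereas the
synthetic records begin exactly at task onset, where an artifact would be
indistinguishable from filter initialization.

Determinism: every generator output is a pure function of configuration
and seed (numpy `SeedSequence` spawning per subject/trial/stream), and
the CSV writers use a fixed float format, so reruns are byte-identical.

## Signal metrics (`hapticlab.metrics`)

* EMG chain: zero-phase 2nd-order Butterworth band-pass 30–450 Hz →
  full-wave rectification → zero-phase 2nd-order Butterworth low-pass
  6 Hz → MVC normalization → moving median.  "Zero-phase 2nd-order"
  means a 2nd-order design run forward–backward (4th-order magnitude, no
  group delay); the lag of a tone-burst envelope is ≤ 1 sample.
* Moving-median window: 0.4 s.  The median runs after the 6 Hz low-pass,
  where a 5 ms spike has been smeared to roughly the low-pass impulse
  width (~0.2 s); the window is wider than twice that smear (so the bump
  is rejected) yet much shorter than the task phases (so plateaus
  survive).  With this chain the envelope of zero-noise synthetic EMG is
  recovered at r > 0.99 per channel, and r ≳ 0.97 at default noise and
  artifact rates.
* Phase segmentation: the five per-repetition game events map to phase
  intervals; rest is the 5 s after release.  Boundaries convert to
  sample indices with half-up rounding, inclusive start / exclusive end;
  repetitions with missing or mis-ordered events are excluded and
  logged, never imputed.
* SPARC: arc length of the peak-normalized magnitude spectrum
  (zero-padded FFT, pad exponent 4) up to an adaptive cutoff — the last
  frequency below 20 Hz with normalized magnitude ≥ 0.05 — negated.
  Scale- and time-reversal-invariant; more sub-movements ⇒ more negative.
* CCI: Falconer–Winter overlap form `100·2·Σmin(a,b)/Σ(a+b)` over the
  interval, bounded in [0, 100]; chosen because condition-level values
  in the original report (≈24–27) live naturally on this scale.  The
  Rudolph ratio form is available behind `variant="rudolph"`.  Pairs:
  BIC–TRI, BRACH–TRI, FD–ED, DELT_A–DELT_P, PECT–DELT_P, PRON–SUP.
* EMG RMS is computed on the MVC-normalized envelope (consistent with
  reporting normalized RMS); computing it on the band-passed signal
  instead would scale values but not change the nonparametric tests.
* Aggregation: repetitions average within a trial, trials within a
  subject; descriptives report mean, SD and Student-t 95 % CI across
  subjects.

## Synergies (`hapticlab.synergy`)

Envelopes are anti-alias low-passed (4th-order Butterworth at 200 Hz) and
linearly interpolated onto a 500 Hz grid — envelopes are 6 Hz
band-limited, so this decimation is exact in practice; a polyphase
resampler for the 5000/21481 rational ratio would need a ~2×10⁵-tap FIR
for no additional fidelity.  NNMF uses multiplicative updates
(Frobenius), 20 seeded random restarts by default, 2000 iterations, 1e−6
tolerance, keeping the restart with the highest VAF
(`1 − ‖E−WH‖²_F/‖E‖²_F`).  Weight columns are reported ℓ2-normalized with
the scale absorbed into H (VAF-invariant).  VAF curves warm-start each
order from the best (k−1) solution padded with a small random column;
multiplicative updates never worsen their initialization, so the curve is
monotone non-decreasing by construction.

Order selection: criterion A = smallest k with (median) VAF > 0.90;
criterion B = smallest k whose increment VAF(k+1)−VAF(k) falls to or
below 0.001 (curves of length 1 satisfy B trivially; a curve still rising
at the last candidate leaves B unmet); the selected order is max(A, B),
falling back to the largest candidate with a warning when neither
criterion is met.  Cohort-wide runs select on the median-across-subjects
curve.  Reordering permutes each subject's synergies by Hungarian
assignment on cosine similarity against a seeded randomly-chosen
reference subject (optimal and deterministic, hence idempotent); sets
with unequal k are truncated to the common minimum with a warning.
Condition-vs-baseline similarity is a per-subject, per-synergy Pearson
test on the 13-muscle weight vectors (weights, not activations, are the
compared objects), with across-subject medians of r and p reported; a
significant test indicates similarity.

## Statistics (`hapticlab.stats`)

Two pre-registered three-condition families (grasp GV/GC/NH,
pronosupination RV/RC/NH).  Per metric × channel × phase: Friedman
chi-square on complete blocks (mid-ranks, tie correction; a fully tied
block is defined as statistic 0, p = 1, which the textbook formula leaves
0/0); pairwise Wilcoxon signed-rank only when the gate passes at 0.05.
The exact Wilcoxon path (n ≤ 12) builds the full null distribution by a
generating-function convolution over Pratt-ranked differences (zeros
ranked then dropped; midranks doubled to keep integer support) and
doubles the smaller tail; n > 12 uses the normal approximation with
continuity correction.  Bonferroni tiers for the three paired tests:
0.017 (*), 0.003 (**), 0.0003 (***), i.e. (0.05, 0.01, 0.001)/3 rounded
at conventional reporting precision.  Effect size defaults to pooled-SD
Cohen's d, with the paired d_z variant behind a flag; the published
per-contrast d values are not arithmetically recoverable from the
published means and SDs under either variant, so no numeric d is treated
as a reference value.  No correction is applied across metrics or phases
(the correction spans only a family's three pairwise tests).  Type-I
behaviour of the gate is property-tested: on exchangeable null cohorts
the gated fraction stays within the binomial 95 % interval of 0.05.

## Problem sizes

The default configuration (9 subjects × 5 conditions × 2 trials × 5
repetitions, all three streams) is what `hapticlab simulate` writes.  The
test suite and the acceptance script run the same code at smaller sizes
chosen as reasonable desk-scale experiments: transient calibration uses
the full default cohort (pose streams only); synergy recovery uses 9
subjects × 1 repetition with 5 NNMF restarts and 1000 iterations;
end-to-end CLI checks use 2–5 subjects with shortened movement phases.
All sizes are stated in the tests themselves.

## Limitations

* The subject model is phenomenological: no musculoskeletal dynamics, no
  learning across trials, no fatigue, and no stable between-subject
  differences (subjects differ only through their seeds), so
  across-subject variance is driven by trial-level noise.
* EMG realism is limited to what the analysis chain observes: a
  band-limited carrier amplitude-modulated by synergy envelopes.  Firing
  statistics, cross-talk, electrode impedance drift and baseline wander
  are absent, so passing tests certify the pipeline's arithmetic, not its
  behaviour on every pathology of real recordings.
* The device model is linear; amplifier current limits enter only as the
  3.68 N output saturation, and the belt's visco-elastic high-frequency
  behaviour beyond the fitted second order is not represented.
* Condition effects on kinematic smoothness/acceleration contrasts are
  not built into the generator; only pose-level effects (bias, variance,
  settling) are calibrated, so group-level kinematic contrasts of the
  original study are out of scope for the synthetic cohort.
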
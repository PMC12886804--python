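# hapticlab

Wearable haptic-guidance rendering and upper-limb motor-control analysis.

`hapticlab` implements, end to end, the computational core of a
wearable-armband guidance experiment: a belt device worn on the arm renders
directional tactile cues (continuous clenching / lateral skin stretch, with
an optional vibrotactile component) that guide hand grasping and forearm
pronosupination toward a reference pose during a virtual pick-and-pour
exercise.  The package is aimed at motor-control and rehabilitation
researchers who want a tested, seeded reference implementation of the whole
chain — force rendering, device dynamics, surface-EMG and kinematics
metrics, muscle-synergy extraction, and the repeated-measures statistics —
that runs without any human recordings, on a synthetic subject cohort.

## The model in brief

**Force rendering.**  Each of the two belt motors receives

```
F_{a,b} = A_{a,b} · e_p · ( K_c · e_b + K_v · sin(2π f_v t) )
```

where `e_p` is the pose error (grasp-ratio difference, or pronation error
in degrees), `e_b` the belt-displacement error of the low-level impedance
loop (mm), `K_c` the impedance stiffness (N/mm) and `K_v`, `f_v` the
vibrotactile amplitude (N) and frequency (Hz).  Five conditions are
pre-registered (GC, GV, RC, RV, NH); each motor saturates at 3.68 N.  The
actuator+belt is an underdamped second-order system calibrated from its
bench step response (49.4 % overshoot, 81 Hz damped oscillation, 2.14 N
steady state at 1.85 V).

**Synthetic cohort.**  Subjects are delayed second-order error-correctors:
at each task-phase boundary a pose target is drawn (reference + condition
-dependent bias and endpoint noise) and tracked after a reaction delay.
Guidance suppresses the no-haptics bias and shrinks endpoint variance,
with vibrotactile+continuous (V) stronger than continuous alone (C).  Each
trial carries synchronized 100 Hz pose, 240 Hz segment kinematics and
2148.1 Hz 13-channel EMG generated from a known synergy basis.

**Analysis.**  EMG: zero-phase 2nd-order Butterworth band-pass 30–450 Hz,
rectification, zero-phase 2nd-order low-pass 6 Hz, MVC normalization and
moving-median artifact removal.  Per-phase metrics: RMS (EMG and segment
velocity/acceleration), range of motion, SPARC smoothness, Falconer–Winter
co-contraction.  Synergies: NNMF at 500 Hz with best-of-restarts
multiplicative updates, VAF-threshold (0.90) + slope-threshold (0.001)
order selection, Hungarian reordering against a seeded reference subject,
and per-synergy Pearson comparison against the no-haptics baseline.
Statistics: Friedman gate (p < 0.05) per metric/channel/phase, pairwise
Wilcoxon signed-rank (exact for n ≤ 12), Bonferroni tiers
0.017 / 0.003 / 0.0003 for three paired tests, Cohen's d and Student-t
95 % CIs.

## Worked example

`examples/device_characterization.py` calibrates the belt model from the
bench measurements and reruns the two bench experiments:

```
damping ratio from 49.4% overshoot: zeta = 0.2190
step response @ 1.85 V: peak 3.197 N, steady state 2.14 N, overshoot 49.4%,
rise 3.55 ms, 2% settling 33.0 ms
round-trip damping from measured overshoot: 0.2190
chirp response: flat low-frequency gain 1.157 N/V, resonance peak at 78.7 Hz
```

The simulated peak matches the measured 3.19 N; the chirp response is flat
in the sub-10 Hz band used for continuous modulation and resonates at
`f_n·sqrt(1 − 2ζ²)` of the fitted system.

`examples/guided_transients.py` measures how fast the simulated cohort's
median pose error settles below 10 % of the reference after guidance
onset:

```
settle time of the cohort-median |error| to within 10% of the reference:
  GV:  1.18 s   (individual subjects reaching 10%: 8/9)
  GC:   never   (individual subjects reaching 10%: 1/9)
  RV:  0.77 s   (individual subjects reaching 10%: 9/9)
  RC:   never   (individual subjects reaching 10%: 2/9)
```

Only the combined continuous+vibrotactile feedback reaches the 10 % band
within the guided phase — the behaviour the cohort generator is calibrated
to.  The remaining examples cover force rendering
(`force_rendering.py`), synergy recovery from synthetic EMG
(`synergy_recovery.py`, VAF curve `0.9157 0.9874 0.9984 …` selecting the
generative k = 3 with matched cosines ≥ 0.986) and the full statistics
battery (`statistics_battery.py`).

## Command line

A thin CLI wraps the library for batch use:

```bash
hapticlab simulate    --config cfg.yaml --out session/        # write a cohort
hapticlab analyze     --data session/ --out results/          # metrics+synergy+stats
hapticlab characterize --experiment both --out bench/         # bench experiments
hapticlab stats       --metrics results/metrics.csv --out st/ # battery only
```

Sessions are plain CSV/JSON
(`subject_XX/trial_YY_{pose,imu,emg}.csv` + `manifest.json`); two runs
from the same configuration are byte-identical.

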
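"""Synthetic multi-subject cohort for the guided pick-and-pour task.

No raw recordings from the human study are publicly available, so every
downstream stage (preprocessing, per-phase metrics, synergy extraction,
statistics) is exercised on a simulated cohort whose *direction* of effects
matches the study design: haptic guidance pulls the executed pose toward
the reference and shrinks trial-to-trial variability, with the combined
continuous+vibrotactile modality stronger than continuous alone, and no
guidance leaving a systematic over-closure / over-pronation bias.

Each simulated trial contains three synchronized streams:

* hand pose at 100 Hz -- grasp ratio in [0, 1] and pronation angle (deg),
* segment kinematics at 240 Hz -- minimum-jerk transport profiles for
  upper arm / forearm / hand plus joint angles,
* 13-channel surface EMG at 2148.1 Hz generated from a known synergy basis
  (weights x phase-keyed activations) amplitude-modulating a 30-450 Hz
  band-limited carrier, with optional artifact spikes.

The subject is modelled as a delayed, underdamped second-order
error-corrector: at each task-phase boundary a new pose target is drawn
(reference plus condition-dependent bias and endpoint noise) and tracked
after a reaction delay.  This is a behavioural stand-in, not a
biomechanical model; its defaults are calibrated so the median guided
transients settle below 10% of the reference within the times observed in
the study (2.5 s grasp, 1.2 s pronosupination).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .conditions import (
    CONDITION_NAMES,
    condition_modality,
    condition_task,
    get_profile,
)

__all__ = [
    "FS_POSE",
    "FS_IMU",
    "FS_EMG",
    "MUSCLES",
    "SEGMENTS",
    "JOINTS",
    "TaskReference",
    "SubjectParams",
    "SynergyGroundTruth",
    "TrialData",
    "minimum_jerk_profile",
    "generate_pose_trace",
    "generate_kinematics",
    "generate_emg",
    "generate_trial",
    "generate_session",
]

FS_POSE = 100.0     # hand-tracking rate, Hz
FS_IMU = 240.0      # motion-capture rate, Hz
FS_EMG = 2148.1     # surface-EMG sampling rate, Hz

MUSCLES = [
    "BIC", "TRI", "BRACH", "PRON", "SUP", "FD", "ED", "AP",
    "DELT_A", "DELT_M", "DELT_P", "INFRAS", "PECT",
]
SEGMENTS = ["upper_arm", "forearm", "hand"]
JOINTS = ["shoulder_rotation", "wrist_pronosupination"]

#: event names marking the five phase starts of one repetition
EVENT_NAMES = ["grab", "over_cauldron", "pour_start", "pour_stop", "release"]


@dataclass(frozen=True)
class TaskReference:
    """Setpoints and timing of the virtual pick-and-pour exercise.

    ``grasp_ref`` is the reference hand-closure ratio, ``pronation_ref``
    the pouring angle in degrees, ``phase_durations`` the five phase
    lengths in seconds (the fifth phase is the 5 s rest between
    repetitions).
    """

    grasp_ref: float = 0.5
    pronation_ref: float = 60.0
    phase_durations: tuple[float, ...] = (2.0, 3.0, 3.0, 2.0, 5.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.grasp_ref <= 1.0:
            raise ValueError("grasp_ref must lie in [0, 1]")
        if len(self.phase_durations) != 5 or any(
            d <= 0 for d in self.phase_durations
        ):
            raise ValueError("phase_durations must be 5 positive values")

    @property
    def repetition_duration(self) -> float:
        return float(sum(self.phase_durations))


@dataclass(frozen=True)
class SubjectParams:
    """Behavioural parameters of the simulated subject.

    ``response_f_*`` (Hz) and ``response_zeta`` set the natural frequency
    and damping of the second-order error-correction dynamics per task;
    ``reaction_delay`` delays target switches.  ``nh_bias_*`` are the
    systematic endpoint biases without guidance; ``sigma_*`` map the
    modality key ('V', 'C', 'NH') to the trial-to-trial endpoint SD;
    ``salience_*`` map 'V'/'C' to the fraction of bias suppressed when the
    corresponding feedback is active.  ``tremor_*`` are within-trial pose
    noise SDs.
    """

    reaction_delay: float = 0.3
    response_zeta: float = 0.35
    response_f_grasp: float = 0.8
    response_f_pronation: float = 1.5
    nh_bias_grasp: float = 0.2
    nh_bias_pronation: float = 30.0
    sigma_grasp: dict = field(
        default_factory=lambda: {"V": 0.04, "C": 0.08, "NH": 0.12}
    )
    sigma_pronation: dict = field(
        default_factory=lambda: {"V": 3.7, "C": 11.7, "NH": 20.6}
    )
    salience_grasp: dict = field(default_factory=lambda: {"V": 1.0, "C": 0.5})
    salience_pronation: dict = field(default_factory=lambda: {"V": 1.0, "C": 0.75})
    tremor_grasp: float = 0.01
    tremor_pronation: float = 1.0
    imu_pos_noise: float = 0.002   # m, smooth tracking noise on segments
    imu_angle_noise: float = 0.5   # deg

    def __post_init__(self) -> None:
        if self.reaction_delay < 0:
            raise ValueError("reaction_delay must be >= 0")
        for sig in (self.sigma_grasp, self.sigma_pronation):
            if not (0 <= sig["V"] <= sig["C"] <= sig["NH"]):
                raise ValueError(
                    "endpoint SDs must satisfy sigma_V <= sigma_C <= sigma_NH"
                )
        if self.tremor_grasp < 0 or self.tremor_pronation < 0:
            raise ValueError("tremor SDs must be >= 0")


def _default_w_true() -> np.ndarray:
    # columns: hand grasp / arm transport / pronosupination
    w = np.array(
        [
            # s1    s2    s3
            [0.20, 0.50, 0.30],  # BIC
            [0.10, 0.60, 0.10],  # TRI
            [0.30, 0.20, 0.50],  # BRACH
            [0.05, 0.05, 0.80],  # PRON
            [0.05, 0.05, 0.60],  # SUP
            [0.80, 0.10, 0.10],  # FD
            [0.50, 0.10, 0.20],  # ED
            [0.60, 0.05, 0.10],  # AP
            [0.10, 0.70, 0.15],  # DELT_A
            [0.05, 0.50, 0.10],  # DELT_M
            [0.05, 0.45, 0.05],  # DELT_P
            [0.10, 0.40, 0.20],  # INFRAS
            [0.15, 0.55, 0.10],  # PECT
        ]
    )
    return w / np.linalg.norm(w, axis=0, keepdims=True)


#: per-synergy activation level in each of the five phases
_H_PHASE_LEVELS = np.array(
    [
        # ph1   ph2   ph3   ph4   ph5
        [0.80, 0.50, 0.50, 0.50, 0.05],  # hand grasp synergy
        [0.60, 0.80, 0.10, 0.80, 0.05],  # arm transport synergy
        [0.05, 0.30, 0.90, 0.20, 0.02],  # pronosupination synergy
    ]
)


@dataclass(frozen=True)
class SynergyGroundTruth:
    """Known synergy basis used to generate the synthetic EMG.

    ``W_true`` is muscles x k, non-negative with unit-norm columns;
    ``phase_levels`` is k x 5 activation amplitude per task phase;
    ``envelope_scale`` sets the overall envelope magnitude in MVC units;
    ``noise_sd`` is the envelope noise SD as a fraction of the signal RMS;
    ``artifact_rate`` the expected number of 5 ms artifact spikes per
    second of raw EMG.
    """

    W_true: np.ndarray = field(default_factory=_default_w_true)
    phase_levels: np.ndarray = field(default_factory=lambda: _H_PHASE_LEVELS.copy())
    envelope_scale: float = 0.02
    noise_sd: float = 0.05
    artifact_rate: float = 0.2

    def __post_init__(self) -> None:
        w = np.asarray(self.W_true, dtype=float)
        if w.ndim != 2 or w.shape[1] < 1:
            raise ValueError("W_true must be a 2-D muscles x k matrix")
        if (w < 0).any():
            raise ValueError("W_true must be non-negative")
        if np.asarray(self.phase_levels).shape != (w.shape[1], 5):
            raise ValueError("phase_levels must be k x 5")

    @property
    def k(self) -> int:
        return int(np.asarray(self.W_true).shape[1])


@dataclass
class TrialData:
    """Synchronized pose / kinematics / EMG streams of one trial."""

    subject_id: int
    trial_id: int
    condition: str
    seed: int
    reference: TaskReference
    pose_time: np.ndarray
    grasp: np.ndarray
    pronation: np.ndarray
    pose_phase: np.ndarray
    imu_time: np.ndarray
    imu: dict            # '<segment>_pos|vel|acc' and joint-angle arrays
    imu_phase: np.ndarray
    emg_time: np.ndarray
    emg: np.ndarray      # samples x muscles, raw (carrier-modulated)
    emg_phase: np.ndarray
    events: list         # per repetition: {event name: time_s}
    envelope_true: np.ndarray | None = None  # samples x muscles, MVC units
    H_true: np.ndarray | None = None         # k x samples


# ---------------------------------------------------------------------------
# pose generation


def _phase_labels(durations, fs: float, repetitions: int) -> np.ndarray:
    """Integer phase label (1..5, repeating) per sample at rate ``fs``."""
    rep = sum(durations)
    n = int(round(rep * repetitions * fs))
    t = np.arange(n) / fs
    within = t % rep
    edges = np.cumsum((0.0,) + tuple(durations))
    return np.digitize(within, edges[1:-1]) + 1


def _second_order_track(
    target: np.ndarray, f_n: float, zeta: float, dt: float
) -> np.ndarray:
    """Track a piecewise-constant target with exact ZOH discretization."""
    wn = 2.0 * math.pi * f_n
    A = np.array([[0.0, 1.0], [-(wn**2), -2.0 * zeta * wn]])
    B = np.array([[0.0], [wn**2]])
    Ad, Bd, *_ = signal.cont2discrete(
        (A, B, np.eye(2), np.zeros((2, 1))), dt, method="zoh"
    )
    out = np.empty(len(target))
    x = np.zeros(2)
    for i, u in enumerate(target):
        out[i] = x[0]
        x = Ad @ x + Bd[:, 0] * u
    return out


def _phase_targets(
    condition: str,
    ref: TaskReference,
    subj: SubjectParams,
    rng: np.random.Generator,
    repetitions: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-repetition, per-phase pose targets for both DoFs.

    Returns (grasp_targets, pronation_targets), each repetitions x 5.
    """
    task = condition_task(condition)
    modality = condition_modality(condition)

    nominal_grasp = np.array([ref.grasp_ref] * 4 + [0.0])
    nominal_pron = np.array(
        [0.0, 0.6 * ref.pronation_ref, ref.pronation_ref, 0.25 * ref.pronation_ref, 0.0]
    )
    # phases in which guidance is rendered, and in which the unguided bias acts
    guided_grasp = {2, 3, 4}
    guided_pron = {2, 3}
    biased_grasp = {1, 2, 3, 4}   # everyone over-closes when grabbing (phase 1)
    biased_pron = {3}

    def draw(dof: str) -> np.ndarray:
        if dof == "grasp":
            nominal, guided_set, biased_set = nominal_grasp, guided_grasp, biased_grasp
            bias, sigma, salience = subj.nh_bias_grasp, subj.sigma_grasp, subj.salience_grasp
            dof_guided = task == "grasp"
        else:
            nominal, guided_set, biased_set = nominal_pron, guided_pron, biased_pron
            bias, sigma, salience = (
                subj.nh_bias_pronation, subj.sigma_pronation, subj.salience_pronation,
            )
            dof_guided = task == "pronosupination"
        targets = np.empty((repetitions, 5))
        for r in range(repetitions):
            for p in range(1, 6):
                b = bias if p in biased_set else 0.0
                guided = dof_guided and p in guided_set
                if guided:
                    offset = (1.0 - salience[modality]) * b + rng.normal(
                        0.0, sigma[modality]
                    )
                elif nominal[p - 1] == 0.0:
                    offset = rng.normal(0.0, 0.1 * sigma["NH"])
                else:
                    offset = b + rng.normal(0.0, sigma["NH"])
                targets[r, p - 1] = nominal[p - 1] + offset
        return targets

    return draw("grasp"), draw("pronation")


def generate_pose_trace(
    condition: str,
    ref: TaskReference,
    subj: SubjectParams,
    seed,
    repetitions: int = 5,
):
    """Simulate the 100 Hz hand-pose streams for one trial.

    Returns ``(time, grasp, pronation, phase, events)`` where ``events`` is
    a list of per-repetition dicts mapping the five phase-start event names
    to times in seconds.  The trace is a pure function of
    ``(condition, ref, subj, seed, repetitions)``.
    """
    get_profile(condition)  # validates the name
    rng = np.random.default_rng(seed)
    dt = 1.0 / FS_POSE
    durations = ref.phase_durations
    phase = _phase_labels(durations, FS_POSE, repetitions)
    n = len(phase)
    t = np.arange(n) / FS_POSE

    grasp_targets, pron_targets = _phase_targets(condition, ref, subj, rng, repetitions)

    # piecewise-constant target signals, then reaction-delay shift
    rep_len = ref.repetition_duration

    def build_target(per_phase: np.ndarray) -> np.ndarray:
        edges = np.cumsum((0.0,) + tuple(durations))
        within = t % rep_len
        rep_idx = np.minimum((t / rep_len).astype(int), repetitions - 1)
        ph_idx = np.digitize(within, edges[1:-1])
        return per_phase[rep_idx, ph_idx]

    delay_n = int(round(subj.reaction_delay * FS_POSE))

    def delayed(sig_: np.ndarray) -> np.ndarray:
        if delay_n == 0:
            return sig_
        return np.concatenate([np.zeros(delay_n), sig_[:-delay_n]])

    grasp = _second_order_track(
        delayed(build_target(grasp_targets)),
        subj.response_f_grasp, subj.response_zeta, dt,
    )
    pron = _second_order_track(
        delayed(build_target(pron_targets)),
        subj.response_f_pronation, subj.response_zeta, dt,
    )

    grasp = grasp + rng.normal(0.0, subj.tremor_grasp, n)
    pron = pron + rng.normal(0.0, subj.tremor_pronation, n)
    grasp = np.clip(grasp, 0.0, 1.0)

    events = []
    for r in range(repetitions):
        t0 = r * rep_len
        starts = np.cumsum((0.0,) + tuple(durations[:-1]))
        events.append(
            {name: float(t0 + s) for name, s in zip(EVENT_NAMES, starts)}
        )
    return t, grasp, pron, phase, events


# ---------------------------------------------------------------------------
# kinematics


def minimum_jerk_profile(distance: float, duration: float, t: np.ndarray):
    """Closed-form minimum-jerk displacement, velocity and acceleration.

    For a point-to-point move of ``distance`` in ``duration``, the peak
    speed is ``1.875 * distance / duration``.  ``t`` is clipped to
    [0, duration].
    """
    tau = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
    pos = distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = distance / duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    acc = distance / duration**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    return pos, vel, acc


#: net displacement of each segment in each phase, m (sums to 0 per repetition)
_SEGMENT_TRANSPORT = {
    "hand":      (0.30, 0.40, 0.05, -0.75, 0.0),
    "forearm":   (0.20, 0.25, 0.03, -0.48, 0.0),
    "upper_arm": (0.08, 0.10, 0.01, -0.19, 0.0),
}
#: shoulder-rotation excursion per phase, deg
_SHOULDER_ROTATION = (10.0, 20.0, -5.0, -25.0, 0.0)


def _smooth_noise(rng, n: int, fs: float, sd: float, cutoff: float = 8.0):
    """Band-limited Gaussian noise with the requested marginal SD."""
    if sd == 0.0 or n < 20:
        return np.zeros(n)
    sos = signal.butter(2, cutoff, fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    rms = np.sqrt(np.mean(x**2))
    return x * (sd / rms) if rms > 0 else x


def generate_kinematics(
    pose_time: np.ndarray,
    pronation: np.ndarray,
    ref: TaskReference,
    subj: SubjectParams,
    seed,
    repetitions: int | None = None,
):
    """Derive the 240 Hz segment-kinematics streams from a pose trace.

    Segments follow minimum-jerk transport profiles per phase with additive
    smooth tracking noise; the wrist pronosupination angle resamples the
    100 Hz pronation trace.  Velocities are forward differences of the
    positions (and accelerations of the velocities), so the rectangle-rule
    integral of each velocity exactly equals the net position change.

    Returns ``(time, streams, phase)`` with ``streams`` mapping
    ``'<segment>_pos|vel|acc'`` and joint names to arrays.
    """
    rng = np.random.default_rng(seed)
    total = float(pose_time[-1]) + 1.0 / FS_POSE
    if repetitions is None:
        repetitions = int(round(total / ref.repetition_duration))
    n = int(round(total * FS_IMU))
    t = np.arange(n) / FS_IMU
    dt = 1.0 / FS_IMU
    durations = ref.phase_durations
    phase = _phase_labels(durations, FS_IMU, repetitions)[:n]

    edges = np.cumsum((0.0,) + tuple(durations))
    streams: dict[str, np.ndarray] = {}

    def transport(amplitudes) -> np.ndarray:
        pos = np.zeros(n)
        base = 0.0
        for r in range(repetitions):
            t0 = r * ref.repetition_duration
            for p in range(5):
                seg = (t >= t0 + edges[p]) & (t < t0 + edges[p + 1])
                if not seg.any():
                    continue
                d, dur = amplitudes[p], durations[p]
                move, _, _ = minimum_jerk_profile(d, dur, t[seg] - (t0 + edges[p]))
                pos[seg] = base + move
                base = base + d
            after = t >= (r + 1) * ref.repetition_duration
            pos[after] = base
        return pos

    for segment, amplitudes in _SEGMENT_TRANSPORT.items():
        pos = transport(amplitudes) + _smooth_noise(rng, n, FS_IMU, subj.imu_pos_noise)
        vel = np.zeros(n)
        vel[:-1] = np.diff(pos) / dt
        acc = np.zeros(n)
        acc[:-1] = np.diff(vel) / dt
        streams[f"{segment}_pos"] = pos
        streams[f"{segment}_vel"] = vel
        streams[f"{segment}_acc"] = acc

    streams["shoulder_rotation"] = transport(_SHOULDER_ROTATION) + _smooth_noise(
        rng, n, FS_IMU, subj.imu_angle_noise
    )
    streams["wrist_pronosupination"] = np.interp(
        t, pose_time, pronation
    ) + _smooth_noise(rng, n, FS_IMU, subj.imu_angle_noise)
    return t, streams, phase


# ---------------------------------------------------------------------------
# EMG


def _activation_matrix(
    truth: SynergyGroundTruth,
    ref: TaskReference,
    n: int,
    fs: float,
    repetitions: int,
    ramp: float = 0.3,
) -> np.ndarray:
    """k x n synergy activations: phase-keyed levels with cosine ramps."""
    t = np.arange(n) / fs
    durations = ref.phase_durations
    edges = np.cumsum((0.0,) + tuple(durations))
    H = np.zeros((truth.k, n))
    for r in range(repetitions):
        t0 = r * ref.repetition_duration
        for p in range(5):
            a, b = t0 + edges[p], t0 + edges[p + 1]
            seg = (t >= a) & (t < b)
            if not seg.any():
                continue
            ts = t[seg]
            rise = np.clip((ts - a) / ramp, 0.0, 1.0)
            fall = np.clip((b - ts) / ramp, 0.0, 1.0)
            window = 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall))
            for s in range(truth.k):
                H[s, seg] = truth.phase_levels[s, p] * window
    return H


def generate_emg(
    pose_time: np.ndarray,
    ref: TaskReference,
    truth: SynergyGroundTruth,
    mvc: np.ndarray | float,
    seed,
    repetitions: int | None = None,
):
    """Generate raw 13-channel EMG whose processed envelope is known.

    The envelope ``E = W_true @ H + noise`` (clipped at 0, MVC units)
    amplitude-modulates a 30-450 Hz band-limited Gaussian carrier with unit
    mean absolute value, scaled by the per-muscle MVC amplitude, so the
    standard band-pass / rectify / low-pass / MVC-normalize chain recovers
    ``E``.  Sparse 5 ms high-amplitude artifact spikes are injected at
    ``truth.artifact_rate`` per second.

    Returns ``(time, raw, phase, envelope_true, H)`` with ``raw`` shaped
    samples x muscles.
    """
    n_muscles = np.asarray(truth.W_true).shape[0]
    mvc = np.broadcast_to(np.asarray(mvc, dtype=float), (n_muscles,))
    if (mvc <= 0).any():
        raise ValueError("MVC amplitudes must be positive")
    rng = np.random.default_rng(seed)
    total = float(pose_time[-1]) + 1.0 / FS_POSE
    if repetitions is None:
        repetitions = int(round(total / ref.repetition_duration))
    n = int(round(total * FS_EMG))
    t = np.arange(n) / FS_EMG
    phase = _phase_labels(ref.phase_durations, FS_EMG, repetitions)[:n]

    H = _activation_matrix(truth, ref, n, FS_EMG, repetitions)
    envelope = (truth.W_true * truth.envelope_scale) @ H  # muscles x n
    if truth.noise_sd > 0:
        rms = np.sqrt(np.mean(envelope**2, axis=1, keepdims=True))
        envelope = envelope + rng.normal(0.0, 1.0, envelope.shape) * (
            truth.noise_sd * rms
        )
    envelope = np.clip(envelope, 0.0, None)

    sos = signal.butter(4, [30.0, 450.0], btype="bandpass", fs=FS_EMG, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, (n_muscles, n)), axis=1)
    carrier /= np.mean(np.abs(carrier), axis=1, keepdims=True)

    raw = (envelope * carrier * mvc[:, None]).T  # samples x muscles

    # Artifacts stay clear of the first/last 0.5 s: real recordings start
    # before the task and that settling margin is trimmed when streams are
    # synchronized, so edge spikes never reach the analysis chain.
    n_spikes = rng.poisson(truth.artifact_rate * total)
    spike_len = max(int(round(0.005 * FS_EMG)), 1)
    margin = int(round(0.5 * FS_EMG))
    lo, hi = margin, max(n - spike_len - margin, margin + 1)
    for _ in range(n_spikes):
        ch = rng.integers(0, n_muscles)
        i0 = rng.integers(lo, hi)
        amp = rng.uniform(0.5, 1.5) * mvc[ch] * rng.choice([-1.0, 1.0])
        raw[i0 : i0 + spike_len, ch] += amp

    return t, raw, phase, envelope.T, H


# ---------------------------------------------------------------------------
# session assembly


def generate_trial(
    condition: str,
    subject_id: int,
    trial_id: int,
    seed,
    ref: TaskReference | None = None,
    subj: SubjectParams | None = None,
    truth: SynergyGroundTruth | None = None,
    mvc: float = 1.0,
    repetitions: int = 5,
    with_emg: bool = True,
    with_imu: bool = True,
) -> TrialData:
    """Generate one complete trial (all streams) deterministically."""
    ref = ref or TaskReference()
    subj = subj or SubjectParams()
    truth = truth or SynergyGroundTruth()
    ss = np.random.SeedSequence(seed)
    s_pose, s_imu, s_emg = ss.spawn(3)

    t_pose, grasp, pron, ph_pose, events = generate_pose_trace(
        condition, ref, subj, s_pose, repetitions
    )
    if with_imu:
        t_imu, imu, ph_imu = generate_kinematics(
            t_pose, pron, ref, subj, s_imu, repetitions
        )
    else:
        t_imu, imu, ph_imu = np.empty(0), {}, np.empty(0, dtype=int)
    if with_emg:
        t_emg, raw, ph_emg, env_true, H = generate_emg(
            t_pose, ref, truth, mvc, s_emg, repetitions
        )
    else:
        t_emg = np.empty(0)
        raw = np.empty((0, len(MUSCLES)))
        ph_emg = np.empty(0, dtype=int)
        env_true = H = None

    return TrialData(
        subject_id=subject_id,
        trial_id=trial_id,
        condition=condition,
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31),
        reference=ref,
        pose_time=t_pose, grasp=grasp, pronation=pron, pose_phase=ph_pose,
        imu_time=t_imu, imu=imu, imu_phase=ph_imu,
        emg_time=t_emg, emg=raw, emg_phase=ph_emg,
        events=events,
        envelope_true=env_true, H_true=H,
    )


def _trial_seed(master_seed: int, subject: int, trial_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(subject), int(trial_index)])
    return int(ss.generate_state(1)[0] % 2**31)


def iter_session_trials(
    n_subjects: int,
    n_trials_per_condition: int,
    master_seed: int,
    conditions=CONDITION_NAMES,
    **trial_kwargs,
):
    """Yield every trial of a seeded multi-subject session.

    Condition order is randomized independently per subject (all conditions
    on the same "day", in random order); within a condition the trials are
    consecutive.  Pure function of the arguments.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for subject in range(1, n_subjects + 1):
        order_rng = np.random.default_rng(
            np.random.SeedSequence([int(master_seed), subject, 0xC0])
        )
        order = list(conditions)
        order_rng.shuffle(order)
        trial_index = 0
        for condition in order:
            for _ in range(n_trials_per_condition):
                trial_index += 1
                seed = _trial_seed(master_seed, subject, trial_index)
                yield generate_trial(
                    condition, subject, trial_index, seed, **trial_kwargs
                )


def generate_session(
    out_dir,
    n_subjects: int = 9,
    n_trials_per_condition: int = 2,
    master_seed: int = 0,
    conditions=CONDITION_NAMES,
    overwrite: bool = False,
    **trial_kwargs,
) -> Path:
    """Write a full session to ``out_dir`` and return the manifest path.

    Layout: ``<out>/subject_<id>/trial_<id>_{pose,imu,emg}.csv`` plus a
    top-level ``manifest.json``.  Refuses to write into a non-empty
    directory unless ``overwrite`` is set.
    """
    from . import io as hio  # local import to avoid a cycle

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} is not empty; pass overwrite=True to replace it"
        )
    out.mkdir(parents=True, exist_ok=True)

    entries = []
    for trial in iter_session_trials(
        n_subjects, n_trials_per_condition, master_seed, conditions, **trial_kwargs
    ):
        paths = hio.write_trial(out, trial)
        entries.append(
            {
                "subject": trial.subject_id,
                "trial": trial.trial_id,
                "condition": trial.condition,
                "seed": trial.seed,
                "grasp_ref": trial.reference.grasp_ref,
                "pronation_ref": trial.reference.pronation_ref,
                "phase_durations": list(trial.reference.phase_durations),
                "events": trial.events,
                "rates_hz": {"pose": FS_POSE, "imu": FS_IMU, "emg": FS_EMG},
                "files": {k: str(p.relative_to(out)) for k, p in paths.items()},
            }
        )
    manifest = {
        "master_seed": int(master_seed),
        "n_subjects": int(n_subjects),
        "n_trials_per_condition": int(n_trials_per_condition),
        "conditions": list(conditions),
        "muscles": MUSCLES,
        "software": "hapticlab 0.1.0",
        "trials": entries,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path
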
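"""EMG preprocessing and per-phase biomechanical scalar metrics.

The EMG chain follows the standard surface-EMG practice for upper-limb
recordings: zero-phase second-order Butterworth band-pass 30-450 Hz,
full-wave rectification, zero-phase second-order Butterworth low-pass at
6 Hz, normalization to the per-muscle maximum voluntary contraction (MVC),
and a moving-median stage that removes short high-amplitude artifacts.
"Second-order, zero-phase" means a second-order design applied
forward-backward, i.e. a fourth-order magnitude response with no group
delay.

Scalar metrics per task phase: RMS (EMG envelope and segment
velocity/acceleration), range of motion (max - min of a joint angle),
SPARC spectral-arc-length smoothness of a speed profile, and the
Falconer-Winter co-contraction index for antagonist muscle pairs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .cohort import FS_EMG, MUSCLES

logger = logging.getLogger(__name__)

__all__ = [
    "EnvelopeRecording",
    "PhaseTable",
    "preprocess_emg",
    "segment_phases",
    "compute_rom",
    "compute_sparc",
    "compute_cci",
    "pronation_angle",
    "time_to_bounded_error",
    "aggregate_metrics",
    "descriptives",
    "CCI_PAIRS",
]

#: antagonist pairs evaluated by the co-contraction analysis
CCI_PAIRS = [
    ("BIC", "TRI"),
    ("BRACH", "TRI"),
    ("FD", "ED"),
    ("DELT_A", "DELT_P"),
    ("PECT", "DELT_P"),
    ("PRON", "SUP"),
]


@dataclass
class EnvelopeRecording:
    """MVC-normalized, non-negative EMG envelopes (samples x channels)."""

    envelopes: np.ndarray
    fs: float
    muscles: list = field(default_factory=lambda: list(MUSCLES))

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if (np.asarray(self.envelopes) < 0).any():
            raise ValueError("envelopes must be non-negative")

    def channel(self, muscle: str) -> np.ndarray:
        return self.envelopes[:, self.muscles.index(muscle)]


def preprocess_emg(
    raw: np.ndarray,
    mvc,
    fs: float = FS_EMG,
    *,
    band=(30.0, 450.0),
    lowpass: float = 6.0,
    median_window_s: float = 0.4,
    muscles=None,
) -> EnvelopeRecording:
    """Raw EMG (samples x channels) -> MVC-normalized envelopes.

    ``mvc`` is the per-channel MVC amplitude (scalar broadcastable).  The
    moving median runs *after* the 6 Hz low-pass, so a millisecond-scale
    artifact spike has already been smeared to roughly the low-pass
    impulse-response width; the default 0.4 s window is wider than twice
    that smear (rejecting the bump) yet much shorter than the task phases,
    so envelope plateaus are preserved.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    if not np.isfinite(raw).all():
        raise ValueError("raw EMG contains non-finite samples")
    mvc = np.broadcast_to(np.asarray(mvc, dtype=float), (raw.shape[1],))
    if (mvc <= 0).any():
        raise ValueError("MVC amplitudes must be positive")
    settle = int(3 * fs / band[0])
    if raw.shape[0] < settle:
        warnings.warn("record shorter than 3x the band-pass settling time")

    sos_bp = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    sos_lp = signal.butter(2, lowpass, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos_bp, raw, axis=0)
    x = np.abs(x)
    x = signal.sosfiltfilt(sos_lp, x, axis=0)
    x = x / mvc

    win = int(round(median_window_s * fs))
    if win % 2 == 0:
        win += 1
    if win >= 3:
        x = (
            pd.DataFrame(x)
            .rolling(win, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    x = np.clip(x, 0.0, None)
    return EnvelopeRecording(
        x, fs, list(muscles) if muscles is not None else list(MUSCLES[: raw.shape[1]])
    )


# ---------------------------------------------------------------------------
# phase segmentation


_EVENT_ORDER = ["grab", "over_cauldron", "pour_start", "pour_stop", "release"]


@dataclass
class PhaseTable:
    """Per-repetition (start, end) times of the five task phases."""

    repetitions: list          # list of 5-tuples of (t0, t1), seconds
    excluded: list = field(default_factory=list)

    def sample_intervals(self, fs: float) -> list:
        """Phase boundaries converted to sample indices at rate ``fs``.

        Boundaries use nearest-sample, half-up rounding; intervals are
        inclusive at the start and exclusive at the end.
        """
        out = []
        for rep in self.repetitions:
            out.append(
                [
                    (int(math.floor(a * fs + 0.5)), int(math.floor(b * fs + 0.5)))
                    for a, b in rep
                ]
            )
        return out


def segment_phases(events: list, rest_duration: float = 5.0) -> PhaseTable:
    """Map per-repetition game events onto the five phase intervals.

    ``events`` is a list of dicts with keys grab, over_cauldron,
    pour_start, pour_stop, release (times in s).  Phase *i* spans from
    event *i* to event *i+1*; phase 5 spans ``rest_duration`` after the
    release.  Repetitions with missing or mis-ordered events are excluded
    (logged), never imputed.
    """
    reps, excluded = [], []
    for i, ev in enumerate(events):
        if any(name not in ev for name in _EVENT_ORDER):
            logger.warning("repetition %d excluded: missing event", i)
            excluded.append(i)
            continue
        times = [float(ev[name]) for name in _EVENT_ORDER]
        if any(b <= a for a, b in zip(times, times[1:])):
            logger.warning("repetition %d excluded: events out of order", i)
            excluded.append(i)
            continue
        bounds = times + [times[-1] + rest_duration]
        reps.append(tuple(zip(bounds[:-1], bounds[1:])))
    return PhaseTable(reps, excluded)


# ---------------------------------------------------------------------------
# scalar metrics


def compute_rom(angle: np.ndarray, interval=None) -> float:
    """Range of motion: max - min of a joint-angle trace (deg)."""
    angle = np.asarray(angle, dtype=float)
    if interval is not None:
        angle = angle[interval[0] : interval[1]]
    if angle.size == 0:
        raise ValueError("empty interval")
    return float(np.max(angle) - np.min(angle))


def compute_sparc(
    speed: np.ndarray,
    fs: float,
    fc_max: float = 20.0,
    amp_threshold: float = 0.05,
    pad_exponent: int = 4,
) -> float:
    """Spectral-arc-length smoothness of a speed profile (dimensionless, <= 0).

    Arc length of the magnitude spectrum, normalized to its peak, over an
    adaptive cutoff: the last frequency below ``fc_max`` where the
    normalized magnitude still exceeds ``amp_threshold``.  Scale- and
    time-reversal-invariant; smoother (more unimodal) profiles give values
    closer to 0.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0 or not np.any(speed):
        raise ValueError("SPARC undefined for an all-zero speed trace")
    nfft = int(2 ** math.ceil(math.log2(speed.size) + pad_exponent))
    spectrum = np.abs(np.fft.rfft(speed, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    spectrum = spectrum / np.max(spectrum)

    within = freqs <= fc_max
    sel = within & (spectrum >= amp_threshold)
    if not sel.any():
        raise ValueError("no spectral content below the cutoff")
    i_cut = int(np.nonzero(sel)[0][-1]) + 1
    f_sel = freqs[:i_cut]
    m_sel = spectrum[:i_cut]
    f_range = f_sel[-1] - f_sel[0]
    if f_range == 0:
        return 0.0
    arc = np.sqrt((np.diff(f_sel) / f_range) ** 2 + np.diff(m_sel) ** 2)
    return float(-np.sum(arc))


def compute_cci(
    env_a: np.ndarray,
    env_b: np.ndarray,
    interval=None,
    variant: str = "falconer_winter",
) -> float:
    """Co-contraction index of an antagonist pair over an interval, percent.

    Default is the Falconer-Winter overlap form,
    ``100 * 2 * sum(min(a, b)) / sum(a + b)``, bounded in [0, 100]
    (100 = identical envelopes, 0 = temporally disjoint activation).  The
    Rudolph form ``mean(min/max * (a + b))`` is available as
    ``variant="rudolph"``.
    """
    a = np.asarray(env_a, dtype=float)
    b = np.asarray(env_b, dtype=float)
    if interval is not None:
        a = a[interval[0] : interval[1]]
        b = b[interval[0] : interval[1]]
    if a.shape != b.shape:
        raise ValueError("envelopes must share length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("envelopes must be non-negative")
    total = np.sum(a + b)
    if total == 0:
        raise ValueError("CCI undefined: both envelopes identically zero")
    if variant == "falconer_winter":
        return float(100.0 * 2.0 * np.sum(np.minimum(a, b)) / total)
    if variant == "rudolph":
        hi = np.maximum(a, b)
        ratio = np.divide(
            np.minimum(a, b), hi, out=np.zeros_like(hi), where=hi > 0
        )
        return float(100.0 * np.mean(ratio * (a + b)) / np.mean(a + b))
    raise ValueError(f"unknown CCI variant {variant!r}")


def pronation_angle(lateral_palm: np.ndarray, vertical=(0.0, 0.0, 1.0)) -> float:
    """Angle (deg, in [0, 180]) between the lateral palm vector and vertical."""
    v1 = np.asarray(lateral_palm, dtype=float)
    v2 = np.asarray(vertical, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length vector")
    cos = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def time_to_bounded_error(
    t: np.ndarray,
    error: np.ndarray,
    bound: float,
) -> float:
    """First time after which |error| stays within ``bound`` to the end.

    Used for the guided-transient analysis: the settle time of a pose-error
    trace relative to a fraction of the reference.  Returns ``nan`` if the
    trace never settles.
    """
    inside = np.abs(np.asarray(error, dtype=float)) <= bound
    if not inside[-1]:
        return math.nan
    outside = np.nonzero(~inside)[0]
    if outside.size == 0:
        return float(t[0])
    return float(t[outside[-1] + 1])


# ---------------------------------------------------------------------------
# aggregation


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def trial_phase_metrics(
    trial,
    envelope: EnvelopeRecording,
    phase_table: PhaseTable,
    cci_variant: str = "falconer_winter",
    sparc_params: dict | None = None,
) -> pd.DataFrame:
    """All per-phase scalar metrics of one trial, averaged over repetitions.

    Returns a tidy frame with columns subject, condition, trial, phase,
    metric, channel, value.
    """
    sparc_params = sparc_params or {}
    from .cohort import FS_IMU, FS_POSE, SEGMENTS, JOINTS

    rows = []
    ints_pose = phase_table.sample_intervals(FS_POSE)
    ints_imu = phase_table.sample_intervals(FS_IMU)
    ints_emg = phase_table.sample_intervals(envelope.fs) if envelope else []

    def clipped(iv, n):
        return (min(iv[0], n), min(iv[1], n))

    acc: dict[tuple, list] = {}

    def push(phase, metric, channel, value):
        acc.setdefault((phase, metric, channel), []).append(value)

    for r in range(len(phase_table.repetitions)):
        for p in range(5):
            iv = clipped(ints_pose[r][p], len(trial.grasp))
            if iv[1] > iv[0]:
                push(p + 1, "pose_mean", "grasp_ratio",
                     float(np.mean(trial.grasp[iv[0]:iv[1]])))
                push(p + 1, "pose_mean", "pronation_deg",
                     float(np.mean(trial.pronation[iv[0]:iv[1]])))

            if trial.imu:
                iv = clipped(ints_imu[r][p], len(trial.imu_time))
                if iv[1] > iv[0]:
                    for seg in SEGMENTS:
                        vel = trial.imu[f"{seg}_vel"][iv[0]:iv[1]]
                        push(p + 1, "vel_rms", seg, _rms(vel))
                        push(p + 1, "acc_rms", seg,
                             _rms(trial.imu[f"{seg}_acc"][iv[0]:iv[1]]))
                        speed = np.abs(vel)
                        if np.any(speed):
                            push(p + 1, "sparc", seg,
                                 compute_sparc(speed, FS_IMU, **sparc_params))
                    for joint in JOINTS:
                        push(p + 1, "rom", joint,
                             compute_rom(trial.imu[joint], iv))

            if envelope is not None and len(envelope.envelopes):
                iv = clipped(ints_emg[r][p], envelope.envelopes.shape[0])
                if iv[1] > iv[0]:
                    for m in envelope.muscles:
                        push(p + 1, "emg_rms", m,
                             _rms(envelope.channel(m)[iv[0]:iv[1]]))
                    for a, b in CCI_PAIRS:
                        if a in envelope.muscles and b in envelope.muscles:
                            try:
                                cci = compute_cci(
                                    envelope.channel(a), envelope.channel(b),
                                    iv, cci_variant,
                                )
                            except ValueError:
                                continue
                            push(p + 1, "cci", f"{a}-{b}", cci)

    for (phase, metric, channel), values in acc.items():
        rows.append(
            {
                "subject": trial.subject_id,
                "condition": trial.condition,
                "trial": trial.trial_id,
                "phase": phase,
                "metric": metric,
                "channel": channel,
                "value": float(np.mean(values)),
            }
        )
    return pd.DataFrame(rows)


def aggregate_metrics(trial_frames: list) -> pd.DataFrame:
    """Average per-trial metric frames to one value per subject/condition.

    Repetitions were already averaged per trial; this averages across
    trials, yielding the subject-level table the statistics consume.
    """
    if not trial_frames:
        raise ValueError("no valid trials to aggregate")
    combined = pd.concat(trial_frames, ignore_index=True)
    return (
        combined.groupby(
            ["subject", "condition", "phase", "metric", "channel"], as_index=False
        )["value"]
        .mean()
    )


def descriptives(metrics: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Across-subject mean, SD and Student-t CI per condition/phase/metric."""
    def _desc(group):
        x = group["value"].to_numpy(dtype=float)
        n = len(x)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / math.sqrt(n)
        else:
            half = 0.0
        return pd.Series(
            {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half,
             "n": n}
        )

    out = (
        metrics.groupby(["condition", "phase", "metric", "channel"])
        .apply(_desc, include_groups=False)
        .reset_index()
    )
    return out
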
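"""Force-rendering control law for the five guidance conditions.

The wearable armband tensions a soft belt around the arm with two
direct-drive motors.  Rotating the motors in *opposite* directions clenches
or loosens the belt (normal skin indentation, used for grasp guidance);
rotating them in the *same* direction drags the belt sideways (lateral skin
stretch, used for pronosupination guidance).  The linear pulling force
commanded to motor ``x`` in {a, b} is

    F_x = A_x * e_p * (K_c * e_b + K_v * sin(2 pi f_v t))

where ``e_p`` is the pose error (dimensionless grasp-ratio error for the
grasp task, pronation-angle error in degrees for pronosupination, positive
meaning over-closure / over-pronation), ``e_b`` the belt-displacement error
of the low-level impedance loop in mm, ``K_c`` the impedance stiffness in
N/mm, and ``K_v`` / ``f_v`` the vibrotactile amplitude (N) and frequency
(Hz).  Each motor saturates at ``F_MAX_BELT`` = 3.68 N.

Five feedback conditions are pre-registered:

======  =============================  =====  =====  =====  =====  ====
name    guidance                        A_a    A_b    K_c    K_v   f_v
======  =============================  =====  =====  =====  =====  ====
GC      grasp, continuous               1     -1     0.006   0      --
GV      grasp, continuous+vibration     1     -1     0.6     1.8    60
RC      pronosupination, continuous     0.05   0.05  0.6     0      --
RV      pronosupination, cont.+vibr.    0.05   0.05  0.6     1.8    60
NH      no haptics                      0      0     0       0      --
======  =============================  =====  =====  =====  =====  ====

The 100x gap between the GC and GV stiffness is implemented verbatim from
the device's published parameter set; see ``docs/methods.md`` for the
discussion of this asymmetry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "F_MAX_BELT",
    "CONDITION_NAMES",
    "ConditionProfile",
    "ForceCommand",
    "get_profile",
    "condition_task",
    "condition_modality",
    "compute_motor_forces",
    "belt_setpoint",
    "DEFAULT_BELT_GAIN",
]

#: per-actuator force saturation at nominal current, N
F_MAX_BELT = 3.68

CONDITION_NAMES = ("GC", "GV", "RC", "RV", "NH")

#: default belt-setpoint gains, mm per unit pose error (see belt_setpoint)
DEFAULT_BELT_GAIN = {"clench": 25.0, "stretch": 0.5}


class ConfigError(ValueError):
    """Raised for unknown condition names or invalid configuration."""


@dataclass(frozen=True)
class ConditionProfile:
    """Coefficients of the force-rendering law for one feedback condition.

    ``mode`` is ``"clench"`` (motors counter-rotate, grasp guidance),
    ``"stretch"`` (motors co-rotate, pronosupination guidance) or ``"none"``
    (no haptics).
    """

    name: str
    A_a: float  # pose-error weight, motor A (1/deg for stretch conditions)
    A_b: float  # pose-error weight, motor B
    K_c: float  # impedance stiffness, N/mm
    K_v: float  # vibrotactile amplitude, N
    f_v: float  # vibration frequency, Hz
    mode: str   # clench | stretch | none

    def __post_init__(self) -> None:
        if self.mode not in ("clench", "stretch", "none"):
            raise ConfigError(f"unknown actuation mode {self.mode!r}")
        if self.mode == "clench" and self.A_b != -self.A_a:
            raise ConfigError("clench conditions require A_b = -A_a")


_CONDITIONS = {
    "GC": ConditionProfile("GC", 1.0, -1.0, 0.006, 0.0, 0.0, "clench"),
    "GV": ConditionProfile("GV", 1.0, -1.0, 0.6, 1.8, 60.0, "clench"),
    "RC": ConditionProfile("RC", 0.05, 0.05, 0.6, 0.0, 0.0, "stretch"),
    "RV": ConditionProfile("RV", 0.05, 0.05, 0.6, 1.8, 60.0, "stretch"),
    "NH": ConditionProfile("NH", 0.0, 0.0, 0.0, 0.0, 0.0, "none"),
}


def get_profile(name: str, **overrides: float) -> ConditionProfile:
    """Return the registered profile for ``name``, optionally overridden.

    >>> get_profile("GV").K_v
    1.8
    """
    try:
        profile = _CONDITIONS[name]
    except KeyError:
        raise ConfigError(
            f"unknown condition {name!r}; expected one of {CONDITION_NAMES}"
        ) from None
    return replace(profile, **overrides) if overrides else profile


def condition_task(name: str) -> str | None:
    """Motor task guided by a condition: 'grasp', 'pronosupination' or None."""
    mode = get_profile(name).mode
    return {"clench": "grasp", "stretch": "pronosupination", "none": None}[mode]


def condition_modality(name: str) -> str | None:
    """Feedback modality of a condition: 'C', 'V' or None (no haptics)."""
    profile = get_profile(name)
    if profile.mode == "none":
        return None
    return "V" if profile.K_v > 0 else "C"


@dataclass(frozen=True)
class ForceCommand:
    """Saturated pulling forces commanded to the two belt motors, N."""

    F_a: float
    F_b: float
    saturated_a: bool = False
    saturated_b: bool = False


def _saturate(force: float, f_max: float) -> tuple[float, bool]:
    if force > f_max:
        return f_max, True
    if force < -f_max:
        return -f_max, True
    return force, False


def compute_motor_forces(
    profile: ConditionProfile,
    e_p: float,
    e_b: float,
    t: float,
    *,
    f_max: float = F_MAX_BELT,
    vibration_on: str = "both",
) -> ForceCommand:
    """Evaluate the rendering law for one control tick.

    Parameters
    ----------
    profile
        Condition coefficients (see :func:`get_profile`).
    e_p
        Pose error; dimensionless grasp-ratio error or pronation error in
        degrees.  Positive = over-closure / over-pronation.
    e_b
        Belt displacement error of the impedance loop, mm.
    t
        Time since trial start, s (drives the vibration phase).
    vibration_on
        ``"both"`` applies the vibrotactile term to both motors (default);
        ``"leading"`` applies it only to the motor pulling in the error
        direction (stretch conditions only).

    Notes
    -----
    For the clench conditions the vibration is rendered only in the
    over-closure region (``e_p > 0``), and for negative pose error the
    commanded clenching force is floored at 0 N: once the belt is fully
    loosened the device cannot push on the arm.
    """
    if not all(map(math.isfinite, (e_p, e_b, t))):
        raise ValueError("non-finite input to compute_motor_forces")
    if t < 0:
        raise ValueError("time must be non-negative")
    if profile.mode == "none":
        return ForceCommand(0.0, 0.0)

    vib = profile.K_v * math.sin(2.0 * math.pi * profile.f_v * t)

    if profile.mode == "clench":
        modulation = profile.K_c * e_b + (vib if e_p > 0 else 0.0)
        F_a = profile.A_a * e_p * modulation
        if e_p < 0:
            F_a = max(F_a, 0.0)  # full-loosening floor
        F_b = -F_a
    else:  # stretch
        base = profile.K_c * e_b
        if vibration_on == "both":
            F_a = profile.A_a * e_p * (base + vib)
            F_b = profile.A_b * e_p * (base + vib)
        elif vibration_on == "leading":
            vib_a = vib if e_p >= 0 else 0.0
            vib_b = vib if e_p < 0 else 0.0
            F_a = profile.A_a * e_p * (base + vib_a)
            F_b = profile.A_b * e_p * (base + vib_b)
        else:
            raise ConfigError(f"unknown vibration_on mode {vibration_on!r}")

    F_a, sat_a = _saturate(F_a, f_max)
    F_b, sat_b = _saturate(F_b, f_max)
    return ForceCommand(F_a, F_b, sat_a, sat_b)


def belt_setpoint(
    profile: ConditionProfile,
    e_p: float,
    gain: float | None = None,
) -> float:
    """Belt-displacement setpoint ``d_ref`` (mm), proportional to pose error.

    The high-level renderer maps the pose error onto a belt displacement
    reference tracked by the low-level impedance loop; the sign of the
    setpoint encodes the stretch direction for the pronosupination
    conditions.  The proportional gain defaults to
    ``DEFAULT_BELT_GAIN[mode]`` (25 mm per unit grasp error, 0.5 mm/deg).
    """
    if profile.mode == "none":
        warnings.warn("belt_setpoint called for a no-haptics profile; returning 0")
        return 0.0
    if not math.isfinite(e_p):
        raise ValueError("non-finite pose error")
    if gain is None:
        gain = DEFAULT_BELT_GAIN[profile.mode]
    return gain * e_p
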
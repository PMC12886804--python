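"""Second-order model of the belt actuator and its bench characterization.

The direct-drive motor plus visco-elastic belt behaves, for force output at
the belt, like an underdamped second-order low-pass system.  The model is
calibrated from the bench step response (fractional overshoot, damped
oscillation frequency and steady-state force for a known voltage step) and
simulated at the 1 ms control-loop period using exact zero-order-hold
discretization, so the integration itself adds no error to the reported
metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .conditions import F_MAX_BELT

__all__ = [
    "DeviceModel",
    "StepMetrics",
    "damping_from_overshoot",
    "simulate_step_response",
    "simulate_chirp_response",
]


def damping_from_overshoot(overshoot: float) -> float:
    """Damping ratio of a second-order system from its fractional overshoot.

    Inverts ``overshoot = exp(-zeta*pi/sqrt(1-zeta**2))`` in closed form:
    with ``L = -ln(overshoot)``, ``zeta = L / sqrt(pi**2 + L**2)``.

    >>> round(damping_from_overshoot(math.exp(-math.pi)), 12)  # zeta=1/sqrt(2)
    0.707106781187
    """
    if not 0.0 < overshoot < 1.0:
        raise ValueError("overshoot must lie strictly between 0 and 1")
    log_os = -math.log(overshoot)
    return log_os / math.sqrt(math.pi**2 + log_os**2)


@dataclass(frozen=True)
class DeviceModel:
    """Underdamped second-order belt/actuator model.

    Parameters
    ----------
    zeta
        Damping ratio, 0 < zeta < 1.
    f_d
        Damped oscillation frequency observed in the step response, Hz.
    dc_gain
        Steady-state force per unit input voltage, N/V.
    F_max
        Belt force saturation, N.
    loop_dt
        Control-loop sample time, s.
    msg_rate
        Rate of the haptic reference messages from the application, Hz.
    """

    zeta: float = 0.219
    f_d: float = 81.0
    dc_gain: float = 2.14 / 1.85
    F_max: float = F_MAX_BELT
    loop_dt: float = 1e-3
    msg_rate: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.zeta < 1.0:
            raise ValueError("model must be underdamped: 0 < zeta < 1")
        if self.f_d <= 0 or self.loop_dt <= 0:
            raise ValueError("f_d and loop_dt must be positive")

    @classmethod
    def from_step_characterization(
        cls,
        overshoot: float = 0.494,
        f_d: float = 81.0,
        steady_state: float = 2.14,
        step_amplitude: float = 1.85,
        **kwargs,
    ) -> "DeviceModel":
        """Calibrate the model from bench step-response measurements.

        ``overshoot`` is the fractional first overshoot, ``steady_state``
        the settled force (N) for a step of ``step_amplitude`` volts.
        Defaults reproduce the published characterization of the armband.
        """
        return cls(
            zeta=damping_from_overshoot(overshoot),
            f_d=f_d,
            dc_gain=steady_state / step_amplitude,
            **kwargs,
        )

    @property
    def omega_d(self) -> float:
        """Damped angular frequency, rad/s."""
        return 2.0 * math.pi * self.f_d

    @property
    def omega_n(self) -> float:
        """Natural angular frequency, rad/s."""
        return self.omega_d / math.sqrt(1.0 - self.zeta**2)

    def state_space(self):
        """Continuous (A, B, C, D) matrices of the force transfer function."""
        wn = self.omega_n
        A = np.array([[0.0, 1.0], [-(wn**2), -2.0 * self.zeta * wn]])
        B = np.array([[0.0], [self.dc_gain * wn**2]])
        C = np.array([[1.0, 0.0]])
        D = np.array([[0.0]])
        return A, B, C, D

    def discretize(self):
        """Exact zero-order-hold discretization at ``loop_dt``."""
        Ad, Bd, Cd, Dd, _ = signal.cont2discrete(
            self.state_space(), self.loop_dt, method="zoh"
        )
        return Ad, Bd, Cd, Dd


@dataclass(frozen=True)
class StepMetrics:
    """Scalar summary of a step response.

    ``rise_time`` is the 0-to-100%-of-steady-state crossing (linearly
    interpolated between loop samples), ``transient_time`` the 2% settling
    time, ``overshoot`` the peak excess as a fraction of steady state.
    ``peak = steady_state * (1 + overshoot)`` holds by construction.
    """

    rise_time: float
    transient_time: float
    overshoot: float
    peak: float
    steady_state: float


def _interpolated_peak(t: np.ndarray, y: np.ndarray) -> float:
    """Peak value by local cubic-spline interpolation at the sampled maximum.

    The loop-rate samples straddle the true continuous-time peak; a spline
    through the neighbourhood removes the sampling bias, which would
    otherwise leak into the overshoot (and hence damping) estimates.
    """
    i = int(np.argmax(y))
    lo, hi = max(i - 3, 0), min(i + 4, len(y))
    if hi - lo < 4:
        return float(y[i])
    from scipy.interpolate import CubicSpline

    spline = CubicSpline(t[lo:hi], y[lo:hi])
    dense = np.linspace(t[lo], t[hi - 1], 2001)
    return float(np.max(spline(dense)))


def step_metrics_from_trace(
    t: np.ndarray, force: np.ndarray, steady_state: float
) -> StepMetrics:
    """Compute :class:`StepMetrics` from a simulated force trace."""
    t = np.asarray(t, dtype=float)
    force = np.asarray(force, dtype=float)
    if steady_state == 0.0:
        return StepMetrics(math.nan, 0.0, 0.0, float(np.max(np.abs(force))), 0.0)

    peak = _interpolated_peak(t, force)
    overshoot = max((peak - steady_state) / steady_state, 0.0)
    peak = steady_state * (1.0 + overshoot)

    # rise time: first crossing of the steady-state level
    above = force >= steady_state
    if above.any():
        i = int(np.argmax(above))
        if i == 0:
            rise_time = float(t[0])
        else:
            f0, f1 = force[i - 1], force[i]
            frac = (steady_state - f0) / (f1 - f0)
            rise_time = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    else:
        rise_time = math.nan  # overdamped trace approaching asymptotically

    # 2% settling: first sample after the last excursion outside the band
    outside = np.abs(force - steady_state) > 0.02 * abs(steady_state)
    if outside.any():
        last = int(np.nonzero(outside)[0][-1])
        transient_time = float(t[min(last + 1, len(t) - 1)])
    else:
        transient_time = float(t[0])

    return StepMetrics(rise_time, transient_time, overshoot, peak, steady_state)


def simulate_step_response(
    model: DeviceModel,
    step_amplitude: float,
    duration: float = 0.15,
) -> tuple[pd.DataFrame, StepMetrics]:
    """Simulate the force response to a voltage step.

    Returns a trace frame with columns ``time_s`` and ``force_N`` sampled at
    the control-loop period, and the derived :class:`StepMetrics`.
    ``duration`` must cover at least 5 damped oscillation periods so the
    settling metrics are well defined.
    """
    if duration < 5.0 / model.f_d:
        raise ValueError("duration must cover at least 5 damped periods")
    n = int(round(duration / model.loop_dt)) + 1
    t = np.arange(n) * model.loop_dt
    u = np.full((n, 1), float(step_amplitude))
    Ad, Bd, Cd, Dd = model.discretize()
    _, y, _ = signal.dlsim((Ad, Bd, Cd, Dd, model.loop_dt), u, t=t)
    force = y[:, 0]
    steady_state = model.dc_gain * step_amplitude
    metrics = step_metrics_from_trace(t, force, steady_state)
    trace = pd.DataFrame({"time_s": t, "force_N": force})
    return trace, metrics


def simulate_chirp_response(
    model: DeviceModel,
    f0: float,
    f1: float,
    duration: float,
    amplitude: float,
    *,
    nperseg: int = 8192,
) -> pd.DataFrame:
    """Empirical magnitude response of the model to a logarithmic chirp.

    A log-swept sine of the given voltage amplitude is driven through the
    discretized model; the magnitude response is estimated with the H1
    spectral estimator (cross-spectrum over input auto-spectrum).  Returns a
    frame with columns ``freq_Hz`` and ``magnitude_N_per_V`` restricted to
    the swept band.
    """
    if f0 >= f1:
        raise ValueError("require f0 < f1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    fs = 1.0 / model.loop_dt
    if f1 > 0.5 * fs:
        raise ValueError("f1 exceeds the Nyquist rate of the control loop")

    f_start = max(f0, 0.1)  # a log sweep cannot start at exactly 0 Hz
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    u = amplitude * signal.chirp(t, f0=f_start, f1=f1, t1=duration, method="logarithmic")
    Ad, Bd, Cd, Dd = model.discretize()
    _, y, _ = signal.dlsim((Ad, Bd, Cd, Dd, model.loop_dt), u[:, None], t=t)
    y = y[:, 0]

    freqs, p_uu = signal.welch(u, fs=fs, nperseg=nperseg)
    _, p_uy = signal.csd(u, y, fs=fs, nperseg=nperseg)
    mag = np.abs(p_uy) / np.where(p_uu > 0, p_uu, np.nan)
    band = (freqs >= f0) & (freqs <= f1)
    return pd.DataFrame(
        {"freq_Hz": freqs[band], "magnitude_N_per_V": mag[band]}
    ).dropna()
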
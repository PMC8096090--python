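"""Pressure-controlled ventilator source waveform.

A pressure-controlled ventilator imposes a periodic pressure signal at the
circuit inlet: during inspiration the pressure rises from PEEP to the set
maximum inspiratory pressure ``P_max`` following an underdamped second-order
step response (a small overshoot and fast rise are characteristic of real
machines), and during expiration it falls back to PEEP along a decreasing
sigmoid.  This signal is the boundary condition for both the nonlinear
network simulator and, indirectly, the linear two-compartment model.

Internally everything is in seconds and cmH2O.  The breathing rate ``BR``
is given in breaths per minute, so the cycle period is ``60/BR`` s and the
expiratory time is ``t_ex = 60/BR - t_ins``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, PhaseError

INSPIRATION = "inspiration"
EXPIRATION = "expiration"


@dataclass(frozen=True)
class VentilatorSettings:
    """Breathing-cycle timing and source-pressure shape parameters.

    Parameters
    ----------
    BR : float
        Breathing rate [1/min].
    t_ins : float
        Inspiratory time [s]; must be shorter than the cycle period.
    PEEP : float
        Positive end-expiratory pressure [cmH2O].
    P_max : float
        Maximum (plateau) inspiratory pressure [cmH2O].
    rise_time : float
        Time of the first crossing of ``P_max`` during inspiration [s].
    overshoot_frac : float
        Fractional overshoot of the underdamped step (0.05 = 5%).
    fall_midpoint : float
        Sigmoid midpoint, measured from expiration onset [s].
    fall_steepness : float
        Sigmoid time scale [s].
    """

    BR: float = 18.0
    t_ins: float = 1.0
    PEEP: float = 5.0
    P_max: float = 32.0
    rise_time: float = 0.15
    overshoot_frac: float = 0.05
    fall_midpoint: float = 0.05
    fall_steepness: float = 0.02

    def __post_init__(self):
        if self.BR <= 0:
            raise ConfigError("breathing rate BR must be positive")
        if not 0 < self.t_ins < 60.0 / self.BR:
            raise ConfigError("t_ins must satisfy 0 < t_ins < 60/BR")
        if self.PEEP < 0 or self.P_max <= self.PEEP:
            raise ConfigError("need P_max > PEEP >= 0")
        if self.rise_time <= 0 or self.fall_steepness <= 0:
            raise ConfigError("rise_time and fall_steepness must be positive")
        if self.overshoot_frac < 0:
            raise ConfigError("overshoot_frac must be non-negative")

    @property
    def period(self) -> float:
        """Cycle period 60/BR [s]."""
        return 60.0 / self.BR

    @property
    def t_ex(self) -> float:
        """Expiratory time 60/BR - t_ins [s]."""
        return self.period - self.t_ins

    def damping(self) -> tuple[float, float]:
        """Return ``(zeta, omega_n)`` of the underdamped inspiratory step.

        The damping ratio follows from the overshoot,
        ``zeta = -ln M / sqrt(pi^2 + ln^2 M)`` with ``M = overshoot_frac``,
        and the natural frequency from the first crossing of the setpoint,
        ``omega_n = (pi - acos(zeta)) / (sqrt(1-zeta^2) * rise_time)``.
        A zero overshoot degenerates to the critically damped step, with
        ``rise_time`` interpreted as the 99% settling time.
        """
        m = self.overshoot_frac
        if m < 1e-9:
            # 1-(1+x)e^-x = 0.99 at x ~= 6.6384
            return 1.0, 6.6384 / self.rise_time
        ln = math.log(m)
        zeta = -ln / math.sqrt(math.pi**2 + ln**2)
        omega = (math.pi - math.acos(zeta)) / (
            math.sqrt(1.0 - zeta**2) * self.rise_time
        )
        return zeta, omega


def _step_response(t, zeta, omega):
    """Unit step response of a second-order system (vectorised)."""
    t = np.asarray(t, dtype=float)
    if zeta >= 1.0:
        x = omega * t
        return 1.0 - (1.0 + x) * np.exp(-x)
    wd = omega * math.sqrt(1.0 - zeta**2)
    e = np.exp(-zeta * omega * t)
    return 1.0 - e * (np.cos(wd * t) + (zeta * omega / wd) * np.sin(wd * t))


def inspiratory_pressure(t_in_phase, s: VentilatorSettings):
    """Source pressure during inspiration [cmH2O].

    ``PEEP + (P_max - PEEP) * u(t)`` with ``u`` the underdamped step
    response; ``u(0) = 0`` and ``u`` settles to 1.

    Raises
    ------
    PhaseError
        If ``t_in_phase`` lies outside ``[0, t_ins]``.
    """
    t = np.asarray(t_in_phase, dtype=float)
    if np.any(t < 0) or np.any(t > s.t_ins + 1e-12):
        raise PhaseError("inspiratory_pressure: t outside [0, t_ins]")
    zeta, omega = s.damping()
    out = s.PEEP + (s.P_max - s.PEEP) * _step_response(t, zeta, omega)
    return float(out) if np.isscalar(t_in_phase) else out


def expiratory_pressure(t_in_phase, s: VentilatorSettings):
    """Source pressure during expiration [cmH2O].

    A decreasing logistic sigmoid from about ``P_max`` at expiration onset to
    ``PEEP``, with midpoint ``fall_midpoint`` and time scale
    ``fall_steepness``.
    """
    t = np.asarray(t_in_phase, dtype=float)
    if np.any(t < 0) or np.any(t > s.t_ex + 1e-12):
        raise PhaseError("expiratory_pressure: t outside [0, t_ex]")
    out = s.PEEP + (s.P_max - s.PEEP) / (
        1.0 + np.exp((t - s.fall_midpoint) / s.fall_steepness)
    )
    return float(out) if np.isscalar(t_in_phase) else out


def cycle_phase(t: float, s: VentilatorSettings) -> tuple[str, float]:
    """Fold absolute time into the breathing cycle.

    Returns ``(phase, t_in_phase)``; the first ``t_ins`` seconds of each
    cycle are inspiration, the remainder expiration.
    """
    if t < 0:
        raise PhaseError("cycle_phase: t must be non-negative")
    tm = math.fmod(t, s.period)
    # guard against fmod returning a value indistinguishable from the period
    if tm >= s.period - 1e-12 * s.period:
        tm = 0.0
    if tm < s.t_ins:
        return INSPIRATION, tm
    return EXPIRATION, tm - s.t_ins


def source_pressure(t, s: VentilatorSettings):
    """Composite periodic source pressure at absolute time ``t`` [cmH2O]."""
    if np.isscalar(t):
        phase, tp = cycle_phase(float(t), s)
        if phase == INSPIRATION:
            return inspiratory_pressure(tp, s)
        return expiratory_pressure(tp, s)
    return np.array([source_pressure(float(ti), s) for ti in np.asarray(t)])


def waveform_table(s: VentilatorSettings, n: int = 500):
    """Sample one cycle of the source waveform; columns ``t`` [s], ``P``
    [cmH2O].  Intended for CSV export / inspection."""
    import pandas as pd

    t = np.linspace(0.0, s.period, n, endpoint=False)
    return pd.DataFrame({"t": t, "P": source_pressure(t, s)})
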
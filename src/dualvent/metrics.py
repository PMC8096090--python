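"""Characteristic exhalation times and auto-PEEP metrics.

The expiratory lung-volume trace of the last (periodic) cycle is fitted
with a single exponential decay ``V(t) = a + b*exp(-t/tau)``; the time
constant is compared with the available expiratory time through the
nondimensional ratio ``tau* = 4*tau/t_ex``.  Four time constants empty
about 98% of the tidal volume, so ``tau* > 1`` flags that expiration is
too short — the auto-PEEP regime.  When trapping occurs, the fitted
asymptote ``a`` simply sits above the relaxed volume; it is reported, not
forced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, SolverError
from .simulate import SimResult
from .waveform import VentilatorSettings


@dataclass
class ExpFit:
    """Single-exponential decay fit ``a + b*exp(-t/tau)``."""

    a: float  # asymptote [L]
    b: float  # amplitude [L]
    tau: float  # time constant [s]
    r2: float  # coefficient of determination


@dataclass
class TauStar:
    """Nondimensional exhalation time and the auto-PEEP flag."""

    tau: float  # [s]
    tau_star: float  # 4*tau/t_ex
    autopeep: bool  # tau_star > 1


def extract_expiration(
    result: SimResult, patient: int, from_peak: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Expiratory window of the final cycle, re-zeroed at exhalation onset.

    Returns ``(t_rel, V)`` with ``V`` the absolute lung volume [L]; the
    first sample is the end-inspiratory (peak) volume.  The additive
    offset is irrelevant to the fit form ``a + b*exp(-t/tau)``.

    Because the inspiratory flow is still nonzero when the ventilator
    switches phase, the lung keeps filling briefly while the source
    pressure falls; exhalation proper starts at the volume maximum.  With
    ``from_peak`` (default) the window starts there; otherwise it is the
    raw machine expiratory phase of length ``t_ex``.
    """
    if patient not in (1, 2):
        raise ValueError("patient must be 1 or 2")
    if result.n_cycles < 1 or len(result.t) == 0:
        raise SolverError("result contains no complete cycle")
    s = result.cfg.ventilator
    t0 = (result.n_cycles - 1) * s.period + s.t_ins
    mask = (result.t >= t0 - 1e-9) & (result.t <= t0 + s.t_ex + 1e-9)
    if mask.sum() < 10:
        raise SolverError("expiratory window under-sampled")
    t = result.t[mask]
    v = (result.V1 if patient == 1 else result.V2)[mask]
    if from_peak:
        k = int(np.argmax(v))
        if len(t) - k < 10:  # pathological: peak at the window end
            k = 0
        t, v = t[k:], v[k:]
    return t - t[0], v


def fit_exponential(t: np.ndarray, v: np.ndarray) -> ExpFit:
    """Nonlinear least squares of ``a + b*exp(-t/tau)``.

    Initial guesses: ``a = v[-1]``, ``b = v[0]-v[-1]``, ``tau = span/4``.
    Raises :class:`FitError` on non-convergence or a non-positive fitted
    time constant.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) < 10:
        raise FitError("need at least 10 samples for the exponential fit")
    span = t[-1] - t[0]
    p0 = (v[-1], v[0] - v[-1], max(span / 4.0, 1e-6))

    def model(tt, a, b, tau):
        return a + b * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model,
            t,
            v,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"exponential fit failed: {exc}") from exc
    a, b, tau = (float(x) for x in popt)
    if tau <= 0:
        raise FitError(f"non-positive fitted time constant {tau}")
    resid = v - model(t, a, b, tau)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExpFit(a=a, b=b, tau=tau, r2=min(max(r2, 0.0), 1.0))


def tau_star(tau: float, s: VentilatorSettings) -> TauStar:
    """``tau* = 4*tau/t_ex`` with ``t_ex = 60/BR - t_ins``; auto-PEEP is
    flagged when the ratio exceeds 1."""
    if tau <= 0:
        raise FitError("tau must be positive")
    ts = 4.0 * tau / s.t_ex
    return TauStar(tau=tau, tau_star=ts, autopeep=bool(ts > 1.0))


def asymmetry_coefficient(tau_star_value: float, tau_star_ref: float) -> float:
    """Relative change of ``tau*`` against the equal-driving-pressure
    reference: ``tau*/tau*_ref - 1`` (0 for the reference itself)."""
    if tau_star_ref <= 0:
        raise ValueError("reference tau* must be positive")
    return tau_star_value / tau_star_ref - 1.0


def patient_metrics(result: SimResult, patient: int) -> tuple[ExpFit, TauStar]:
    """Fit one patient's expiration and form the nondimensional metrics."""
    t, v = extract_expiration(result, patient)
    fit = fit_exponential(t, v)
    return fit, tau_star(fit.tau, result.cfg.ventilator)


def metrics_from_timeseries(
    df, s: VentilatorSettings, patient: int
) -> tuple[ExpFit, TauStar]:
    """Metrics from an exported time-series table (columns ``t`` and
    ``V1``/``V2``) rather than an in-memory simulation result.

    The last complete cycle is located from the configured period; the
    expiratory window starts at the volume peak, as in
    :func:`extract_expiration`.
    """
    t = np.asarray(df["t"], dtype=float)
    v = np.asarray(df[f"V{patient}"], dtype=float)
    n_cycles = int(np.floor((t[-1] + 1e-9) / s.period))
    if n_cycles < 1:
        raise SolverError("timeseries shorter than one cycle")
    t0 = (n_cycles - 1) * s.period + s.t_ins
    mask = (t >= t0 - 1e-9) & (t <= t0 + s.t_ex + 1e-9)
    if mask.sum() < 10:
        raise SolverError("expiratory window under-sampled")
    tw, vw = t[mask], v[mask]
    k = int(np.argmax(vw))
    if len(tw) - k < 10:
        k = 0
    fit = fit_exponential(tw[k:] - tw[k], vw[k:])
    return fit, tau_star(fit.tau, s)
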
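"""Parameter estimation for circuit elements.

Two procedures mirror the bench characterisation of the hardware:

* quadratic loss-coefficient fits, ``dP = K q^2``, for filters, one-way
  valves and the in-line PEEP valve, from sampled flow/pressure pairs;
* exhalation-valve resistance estimation: R_V is the argmin of a
  functional J summing, over three probe pressures (each patient's airway
  and the expiratory limb), the time-averaged squared relative error
  between measured traces and the simulator's output at candidate R_V.

Real bench traces are not bundled; :func:`generate_pseudo_experiment`
produces synthetic measurement traces (simulator output plus seeded
multiplicative noise) with known ground truth so the estimators can be
exercised and validated end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import ExhalationValve
from .errors import ConfigError
from .network import CircuitConfig
from .simulate import SimResult, run_to_periodic

#: samples with |measured pressure| below this floor [cmH2O] are excluded
#: from relative errors (the denominators cross zero near PEEP transitions)
PRESSURE_FLOOR = 0.5


@dataclass
class FlowPressureSamples:
    """Bench samples for one element: flow [L/min], pressure drop [cmH2O]."""

    q_lmin: np.ndarray
    dp: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.q_lmin = np.asarray(self.q_lmin, dtype=float)
        self.dp = np.asarray(self.dp, dtype=float)
        if len(self.q_lmin) != len(self.dp) or len(self.q_lmin) < 3:
            raise ConfigError("need >= 3 matching flow/pressure pairs")
        if np.any(self.q_lmin < 0):
            raise ConfigError("flows must be non-negative")


@dataclass
class LossFit:
    """K [cmH2O/(L/min)^2] with residual diagnostics."""

    K: float
    residual_norm: float
    n: int
    label: str = ""


def fit_loss_coefficient(samples: FlowPressureSamples) -> LossFit:
    """No-intercept least squares of ``dP = K q^2``.

    The closed form is ``K = sum(q^2 dP) / sum(q^4)``; K is clipped at
    zero (a negative fit would be unphysical).
    """
    q2 = samples.q_lmin**2
    denom = float(np.sum(q2**2))
    if denom == 0.0:
        raise ConfigError("all-zero flows; cannot fit a loss coefficient")
    k = max(0.0, float(np.sum(q2 * samples.dp) / denom))
    resid = samples.dp - k * q2
    return LossFit(
        K=k,
        residual_norm=float(np.linalg.norm(resid)),
        n=len(samples.dp),
        label=samples.label,
    )


@dataclass
class PressureTraces:
    """Aligned probe-pressure time series [cmH2O].

    ``t`` starts at a cycle onset (phase 0).  Columns: patient-1 airway,
    patient-2 airway, expiratory limb.
    """

    t: np.ndarray
    Paw1: np.ndarray
    Paw2: np.ndarray
    Pesp: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.t)
        for name in ("Paw1", "Paw2", "Pesp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ConfigError("trace lengths differ")
            setattr(self, name, arr)
        if n < 2 or np.any(np.diff(self.t) <= 0):
            raise ConfigError("time grid must be strictly increasing")

    @property
    def sample_period(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "Paw1": self.Paw1, "Paw2": self.Paw2, "Pesp": self.Pesp}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PressureTraces":
        return cls(
            t=df["t"].to_numpy(),
            Paw1=df["Paw1"].to_numpy(),
            Paw2=df["Paw2"].to_numpy(),
            Pesp=df["Pesp"].to_numpy(),
        )


def _resample_probes(res: SimResult, t_grid: np.ndarray) -> tuple[np.ndarray, ...]:
    """Simulator probe pressures interpolated on the experimental grid
    (phase-aligned: both start at cycle onset)."""
    period = res.cfg.ventilator.period
    t0 = (res.n_cycles - 1) * period
    mask = res.t >= t0 - 1e-9
    t_cycle = res.t[mask] - t0
    tg = np.mod(t_grid - t_grid[0], period)
    out = []
    for col in (3, 4, 2):  # Paw1, Paw2, Pesp(expiratory merge)
        out.append(np.interp(tg, t_cycle, res.pressures[mask, col]))
    return tuple(out)


def functional_J(
    R_V: float,
    exp: PressureTraces,
    cfg: CircuitConfig,
    _cache: dict | None = None,
) -> float:
    """Sum over the three probe signals of the time-averaged squared
    relative error between measured and simulated pressure.

    The simulator is run to periodic steady state at the candidate R_V and
    sampled on the experimental time grid; samples where the measured
    pressure magnitude is below :data:`PRESSURE_FLOOR` are dropped from
    the averages.
    """
    c = cfg.with_(exhalation_valve=ExhalationValve(R_V=float(R_V)))
    init = _cache.get("state") if _cache else None
    res = run_to_periodic(c, tol_rel=1e-3, init_state=init)
    if _cache is not None:
        _cache["state"] = res.final_state
    num = _resample_probes(res, exp.t)
    j = 0.0
    for sim, meas in zip(num, (exp.Paw1, exp.Paw2, exp.Pesp)):
        keep = np.abs(meas) > PRESSURE_FLOOR
        if not np.any(keep):
            continue
        rel = (meas[keep] - sim[keep]) / meas[keep]
        j += float(np.mean(rel**2))
    return j


@dataclass
class RVEstimate:
    """Estimated exhalation-valve resistance and the J landscape."""

    R_V: float
    J_min: float
    curve: pd.DataFrame  # columns R_V, J (grid scan)
    at_grid_edge: bool = False


def estimate_RV(
    exp: PressureTraces | list[PressureTraces],
    cfg: CircuitConfig | list[CircuitConfig],
    grid=(0.25, 0.75, 1.25, 1.75, 2.5, 3.5),
    refine_tol: float = 0.02,
) -> RVEstimate:
    """Grid scan plus golden-section refinement of the J minimiser.

    Multiple trace/config pairs (e.g. the three driving-pressure
    experiments) may be pooled: J is then their sum.  A minimum on the
    grid edge is flagged rather than refined blindly.
    """
    exps = exp if isinstance(exp, list) else [exp]
    cfgs = cfg if isinstance(cfg, list) else [cfg] * len(exps)
    caches = [{} for _ in exps]

    def jtot(rv):
        return sum(
            functional_J(rv, e, c, cache)
            for e, c, cache in zip(exps, cfgs, caches)
        )

    grid = sorted(grid)
    jv = [jtot(rv) for rv in grid]
    curve = pd.DataFrame({"R_V": grid, "J": jv})
    k = int(np.argmin(jv))
    if k == 0 or k == len(grid) - 1:
        return RVEstimate(R_V=grid[k], J_min=jv[k], curve=curve, at_grid_edge=True)
    # golden-section search in the bracketing interval
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = grid[k - 1], grid[k + 1]
    c1 = b - invphi * (b - a)
    c2 = a + invphi * (b - a)
    f1, f2 = jtot(c1), jtot(c2)
    while b - a > refine_tol:
        if f1 < f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - invphi * (b - a)
            f1 = jtot(c1)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + invphi * (b - a)
            f2 = jtot(c2)
    rv_best = 0.5 * (a + b)
    return RVEstimate(R_V=rv_best, J_min=jtot(rv_best), curve=curve)


def generate_pseudo_experiment(
    cfg: CircuitConfig,
    R_V_true: float,
    noise_frac: float = 0.0,
    seed: int | None = None,
    sample_rate: float = 100.0,
    n_cycles: int = 1,
) -> PressureTraces:
    """Synthetic measurement traces with known ground truth.

    Runs the simulator at ``R_V_true`` to periodic steady state, samples
    the three probe pressures at ``sample_rate`` Hz over ``n_cycles``
    periodic cycles, and applies multiplicative Gaussian noise of relative
    standard deviation ``noise_frac`` (deterministic given ``seed``).
    """
    if noise_frac < 0:
        raise ConfigError("noise_frac must be non-negative")
    c = cfg.with_(exhalation_valve=ExhalationValve(R_V=float(R_V_true)))
    res = run_to_periodic(c, tol_rel=1e-3)
    period = c.ventilator.period
    t = np.arange(0.0, n_cycles * period, 1.0 / sample_rate)
    paw1, paw2, pesp = _resample_probes(res, np.mod(t, period))
    rng = np.random.default_rng(seed)
    out = []
    for sig in (paw1, paw2, pesp):
        if noise_frac > 0:
            sig = sig * (1.0 + noise_frac * rng.standard_normal(len(sig)))
        out.append(sig)
    return PressureTraces(t=t, Paw1=out[0], Paw2=out[1], Pesp=out[2])
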
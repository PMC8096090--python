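"""Stiff integration of the network over breathing cycles.

The ODE system is integrated phase by phase (inspiration, then expiration)
with a variable-step implicit-capable method (LSODA) at a configurable
relative tolerance (default 1e-3).  The waveform's fast rise and sigmoid
fall make the system stiff, which is why explicit Runge-Kutta is avoided.
Dense output is sampled on a fixed grid of at least 200 points per cycle so
the downstream exponential fits are well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import SolverError
from .network import BRANCH_NAMES, CircuitConfig, Network, assemble_network

PROBE_COLUMNS = (
    "P_src",
    "P_insp_split",
    "P_exp_merge",
    "P_aw1",
    "P_aw2",
)


@dataclass
class SimResult:
    """Sampled time series plus per-cycle summary of one simulation.

    ``t`` is absolute time from the start of the run; cycles begin at
    multiples of the period.  ``flows`` columns follow
    :data:`dualvent.network.BRANCH_NAMES` plus ``lung1``/``lung2``
    (flow into each lung).
    """

    cfg: CircuitConfig
    t: np.ndarray
    pressures: np.ndarray  # (n, 5) columns PROBE_COLUMNS
    flows: np.ndarray  # (n, 9)
    V1: np.ndarray
    V2: np.ndarray
    node_volumes: np.ndarray  # (n, 4)
    cycles: pd.DataFrame
    periodic: bool = False
    n_cycles: int = 0
    cycles_to_converge: int = 0
    final_state: np.ndarray | None = None
    solver_stats: dict = field(default_factory=dict)

    @property
    def flow_names(self):
        return list(BRANCH_NAMES) + ["lung1", "lung2"]

    def pressure(self, name: str) -> np.ndarray:
        return self.pressures[:, PROBE_COLUMNS.index(name)]

    def flow(self, name: str) -> np.ndarray:
        return self.flows[:, self.flow_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for i, c in enumerate(PROBE_COLUMNS):
            cols[c] = self.pressures[:, i]
        for i, c in enumerate(self.flow_names):
            cols["q_" + c] = self.flows[:, i]
        cols["V1"] = self.V1
        cols["V2"] = self.V2
        return pd.DataFrame(cols)

    def last_cycle_mask(self) -> np.ndarray:
        period = self.cfg.ventilator.period
        t0 = (self.n_cycles - 1) * period
        return self.t >= t0 - 1e-9


def _integrate_segment(net: Network, t0, t1, y0, rtol, atol, t_eval, max_step):
    sol = solve_ivp(
        net.rhs,
        (t0, t1),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        max_step=max_step,
        first_step=min(1e-4, (t1 - t0) / 100),
    )
    if not sol.success:
        raise SolverError(f"integrator failed: {sol.message}", t_last=sol.t[-1] if len(sol.t) else t0)
    return sol


def simulate(
    cfg: CircuitConfig,
    n_cycles: int = 1,
    rtol: float = 1e-3,
    atol: float = 1e-8,
    init_state: np.ndarray | None = None,
    samples_per_cycle: int = 300,
    t_offset: float = 0.0,
) -> SimResult:
    """Integrate ``n_cycles`` breathing cycles and sample all probes.

    ``init_state`` continues from a previous run's ``final_state``;
    otherwise lungs start at their nominal-PEEP volumes.  At least 200
    samples per cycle are used regardless of ``samples_per_cycle``.
    """
    if n_cycles < 1:
        raise SolverError("n_cycles must be >= 1")
    net = assemble_network(cfg)
    return _simulate_net(net, n_cycles, rtol, atol, init_state, samples_per_cycle, t_offset)


def _simulate_net(net, n_cycles, rtol, atol, init_state, samples_per_cycle, t_offset=0.0):
    cfg = net.cfg
    s = cfg.ventilator
    period = s.period
    samples_per_cycle = max(200, samples_per_cycle)
    n_ins = max(60, int(round(samples_per_cycle * s.t_ins / period)))
    n_exp = max(120, samples_per_cycle - n_ins)
    y = net.initial_state() if init_state is None else np.array(init_state, dtype=float)

    ts, ys = [], []
    cyc_rows = []
    nfev = 0
    for c in range(n_cycles):
        t0 = t_offset + c * period
        grids = (
            np.linspace(t0, t0 + s.t_ins, n_ins + 1),
            np.linspace(t0 + s.t_ins, t0 + period, n_exp + 1),
        )
        cyc_t, cyc_y = [], []
        for g in grids:
            sol = _integrate_segment(net, g[0], g[-1], y, rtol, atol, g, max_step=0.05)
            y = sol.y[:, -1]
            nfev += sol.nfev
            cyc_t.append(sol.t[:-1])
            cyc_y.append(sol.y[:, :-1])
        cyc_t = np.concatenate(cyc_t)
        cyc_y = np.concatenate(cyc_y, axis=1)
        ts.append(cyc_t)
        ys.append(cyc_y)
        v1 = cyc_y[4]
        v2 = cyc_y[5]
        cyc_rows.append(
            {
                "cycle": c,
                "VT1": float(v1.max() - v1.min()),
                "VT2": float(v2.max() - v2.min()),
                "EEV1": float(y[4]),
                "EEV2": float(y[5]),
            }
        )
    # include the final endpoint sample
    t_end = t_offset + n_cycles * period
    ts.append(np.array([t_end]))
    ys.append(y[:, None])
    t = np.concatenate(ts) - t_offset
    ymat = np.concatenate(ys, axis=1)

    obs = np.empty((len(t), 14))
    for i in range(len(t)):
        obs[i] = net.observe(t[i] + t_offset, ymat[:, i])
    cycles = pd.DataFrame(cyc_rows)
    for pat in (1, 2):
        # end-expiratory pressures at the cycle boundaries
        cycles[f"P_end_exp{pat}"] = [
            float(obs[np.searchsorted(t, (c + 1) * cfg.ventilator.period) - 0, 2 + pat])
            if (c + 1) * cfg.ventilator.period <= t[-1] + 1e-9
            else np.nan
            for c in cycles["cycle"]
        ]
    return SimResult(
        cfg=cfg,
        t=t,
        pressures=obs[:, :5],
        flows=obs[:, 5:14],
        V1=ymat[4],
        V2=ymat[5],
        node_volumes=ymat[:4].T,
        cycles=cycles,
        n_cycles=n_cycles,
        final_state=y.copy(),
        solver_stats={"nfev": int(nfev), "rtol": rtol},
    )


def run_to_periodic(
    cfg: CircuitConfig,
    tol_rel: float = 1e-3,
    max_cycles: int = 50,
    rtol: float = 1e-3,
    atol: float = 1e-8,
    init_state: np.ndarray | None = None,
    samples_per_cycle: int = 300,
) -> SimResult:
    """Iterate cycles until tidal and end-expiratory volumes stop changing.

    Convergence: the max relative change of (VT1, VT2, EEV1, EEV2) between
    consecutive cycles drops below ``tol_rel``.  Returns the final cycle
    with ``periodic=True`` and ``n_cycles`` set to the number of cycles
    actually run; raises :class:`SolverError` with the trend if
    ``max_cycles`` is exhausted.
    """
    net = assemble_network(cfg)
    y = net.initial_state() if init_state is None else np.array(init_state, dtype=float)
    prev = None
    history = []
    for c in range(max_cycles):
        res = _simulate_net(net, 1, rtol, atol, y, samples_per_cycle)
        y = res.final_state
        row = res.cycles.iloc[0]
        cur = np.array([row.VT1, row.VT2, row.EEV1, row.EEV2])
        history.append(cur)
        if prev is not None:
            scale = np.maximum(np.abs(cur), 0.01)
            change = float(np.max(np.abs(cur - prev) / scale))
            if change < tol_rel:
                res.periodic = True
                res.cycles_to_converge = c + 1
                return res
        prev = cur
    trend = np.array(history[-5:])
    raise SolverError(
        f"no periodic steady state within {max_cycles} cycles; "
        f"recent (VT1,VT2,EEV1,EEV2): {trend.round(4).tolist()}"
    )


def derivatives(state: np.ndarray, t: float, network: Network) -> np.ndarray:
    """State derivative at one instant (thin wrapper over the kernel).

    ``state`` is ``[V_split, V_merge, V_aw1, V_aw2, V_lung1, V_lung2]``
    [L]; returns dstate/dt [L/s] from the signed branch-flow balances.
    """
    return network.rhs(t, np.asarray(state, dtype=float))
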
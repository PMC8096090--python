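"""Valve-tuning procedures.

On the bench, each patient's driving pressure is titrated by turning the
pinch-valve knob on their inspiratory branch, and patient 2's PEEP by the
in-line threshold valve.  Numerically, the pinch valve is the quadratic
loss coefficient K of that branch, and these routines play the operator:
iterate K until the end-inspiratory airway pressure minus the nominal PEEP
hits the requested driving pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .components import LocalLoss
from .errors import TuningError
from .network import CircuitConfig
from .simulate import SimResult, run_to_periodic


@dataclass
class PinchTuning:
    """Result of pinch-valve tuning: loss coefficients [cmH2O/(L/s)^2],
    achieved driving pressures [cmH2O], and the tuned periodic run."""

    K: tuple[float, float]
    achieved_DP: tuple[float, float]
    target_DP: tuple[float, float]
    result: SimResult
    n_evals: int


def end_inspiratory_pressures(res: SimResult) -> tuple[float, float]:
    """Patient airway pressures at the end of inspiration of the last
    cycle [cmH2O]."""
    t_ins = res.cfg.ventilator.t_ins
    period = res.cfg.ventilator.period
    t_target = (res.n_cycles - 1) * period + t_ins if res.n_cycles else t_ins
    i = int(np.argmin(np.abs(res.t - t_target)))
    return float(res.pressures[i, 3]), float(res.pressures[i, 4])


def measured_dp(res: SimResult) -> tuple[float, float]:
    """Exhalatory driving pressures DP_i = P_i - PEEP_i.

    P_i is the patient pressure at the initiation of exhalation, i.e. at
    the lung-volume peak of the last cycle.  Lung flow vanishes there, so
    the airway pressure equals the elastic recoil V_peak/C(V_peak) — used
    directly, which is robust to the sampling grid.
    """
    period = res.cfg.ventilator.period
    t0 = (res.n_cycles - 1) * period if res.n_cycles else 0.0
    mask = res.t >= t0 - 1e-9
    out = []
    for v, lung, peep in (
        (res.V1[mask], res.cfg.lung1, res.cfg.peep1),
        (res.V2[mask], res.cfg.lung2, res.cfg.peep2),
    ):
        vpk = float(v.max())
        out.append(vpk / lung.compliance(vpk) - peep)
    return out[0], out[1]


def tune_pinch_valves(
    cfg: CircuitConfig,
    target_DP: tuple[float, float],
    tol: float = 0.1,
    max_evals: int = 40,
    K_init: tuple[float, float] = (0.0, 0.0),
    tol_rel_cycles: float = 5e-3,
    max_cycles: int = 20,
    rtol: float = 1e-3,
) -> PinchTuning:
    """Titrate both pinch valves to per-patient driving-pressure targets.

    Bracketed secant per patient on DP(K), which is monotone decreasing;
    each evaluation runs the circuit to (loose) periodic steady state,
    warm-starting from the previous evaluation's final state.  Raises
    :class:`TuningError` (with the maximum achievable DP) if a target
    exceeds what the unrestricted circuit delivers.
    """
    ks = [max(0.0, K_init[0]), max(0.0, K_init[1])]
    state = None
    hist: list[list[tuple[float, float]]] = [[], []]  # per patient: (K, DP)
    n_evals = 0

    def evaluate(k1, k2):
        nonlocal state, n_evals
        c = cfg.with_(pinch1=LocalLoss(k1), pinch2=LocalLoss(k2))
        res = run_to_periodic(
            c, tol_rel=tol_rel_cycles, max_cycles=max_cycles, rtol=rtol, init_state=state
        )
        state = res.final_state
        n_evals += 1
        return res, measured_dp(res)

    res, dps = evaluate(*ks)
    for i in (0, 1):
        hist[i].append((ks[i], dps[i]))

    # feasibility: with the requested K (usually 0) DP is maximal
    if ks[0] == 0.0 and ks[1] == 0.0:
        for i in (0, 1):
            if dps[i] < target_DP[i] - tol:
                raise TuningError(
                    f"patient {i + 1} target DP {target_DP[i]:.2f} cmH2O unachievable; "
                    f"max achievable ~= {dps[i]:.2f} cmH2O",
                    max_achievable=dps[i],
                )

    while n_evals < max_evals:
        resid = [dps[i] - target_DP[i] for i in (0, 1)]
        for i in (0, 1):
            # fully open valve still short of target -> infeasible
            if ks[i] == 0.0 and resid[i] < -tol:
                raise TuningError(
                    f"patient {i + 1} target DP {target_DP[i]:.2f} cmH2O unachievable; "
                    f"max achievable ~= {dps[i]:.2f} cmH2O",
                    max_achievable=dps[i],
                )
        if all(abs(r) <= tol for r in resid):
            # confirm on a tight periodic run
            final = run_to_periodic(
                cfg.with_(pinch1=LocalLoss(ks[0]), pinch2=LocalLoss(ks[1])),
                tol_rel=1e-3,
                max_cycles=max_cycles + 20,
                rtol=rtol,
                init_state=state,
            )
            fdp = measured_dp(final)
            if all(abs(fdp[i] - target_DP[i]) <= tol for i in (0, 1)):
                return PinchTuning(
                    K=(ks[0], ks[1]),
                    achieved_DP=fdp,
                    target_DP=tuple(target_DP),
                    result=final,
                    n_evals=n_evals,
                )
            state = final.final_state
            dps = fdp
            for i in (0, 1):
                hist[i].append((ks[i], fdp[i]))
            resid = [dps[i] - target_DP[i] for i in (0, 1)]
            if all(abs(r) <= tol for r in resid):  # pragma: no cover - defensive
                return PinchTuning((ks[0], ks[1]), fdp, tuple(target_DP), final, n_evals)
        for i in (0, 1):
            if abs(resid[i]) > tol:
                ks[i] = _next_k(hist[i], target_DP[i], ks[i])
        res, dps = evaluate(*ks)
        for i in (0, 1):
            hist[i].append((ks[i], dps[i]))
    raise TuningError(f"pinch tuning did not converge within {max_evals} evaluations")


def _next_k(hist, target, k_cur):
    """Next pinch K from the (K, DP) history: secant step constrained to
    the current sign-change bracket when one exists."""
    lo = None  # largest K with DP > target
    hi = None  # smallest K with DP < target
    for k, dp in hist:
        if dp >= target and (lo is None or k > lo[0]):
            lo = (k, dp)
        if dp < target and (hi is None or k < hi[0]):
            hi = (k, dp)
    if lo is None:
        # DP everywhere below target so far: open up towards K=0
        return 0.0 if k_cur < 1e-6 else k_cur / 8.0
    if hi is None:
        # need more restriction: grow from the last point
        k, dp = lo
        if k == 0.0:
            return 1.0
        return k * 4.0
    (k0, d0), (k1, d1) = lo, hi
    if d0 != d1:
        k = k0 + (target - d0) * (k1 - k0) / (d1 - d0)
        if lo[0] < k < hi[0]:
            return k
    return 0.5 * (k0 + k1)


@dataclass
class PEEPTuning:
    """Threshold setting plus post-hoc verification."""

    P_thresh: float
    target_PEEP2: float
    measured_PEEP2: float
    within_tolerance: bool


def tune_peep_threshold(
    cfg: CircuitConfig,
    target_PEEP2: float,
    tol: float = 0.2,
    verify: bool = True,
    rtol: float = 1e-3,
) -> tuple[CircuitConfig, PEEPTuning]:
    """Set the in-line threshold so patient 2's PEEP reaches the target.

    The threshold stacks on the ventilator PEEP: ``P_thresh = target -
    PEEP_vent``.  When ``verify`` is set, the circuit is re-run to periodic
    steady state and patient 2's end-expiratory airway pressure is compared
    with the target (the valve's residual quadratic loss can leave a small
    excess; the valve can only add pressure, never remove it).
    """
    peep_vent = cfg.ventilator.PEEP
    if target_PEEP2 < peep_vent - 1e-9:
        raise TuningError(
            f"target PEEP2 {target_PEEP2} below ventilator PEEP {peep_vent}; "
            "the threshold valve can only add"
        )
    p_thresh = max(0.0, target_PEEP2 - peep_vent)
    new_cfg = cfg.with_(peep_valve=cfg.peep_valve.__class__(
        P_thresh=p_thresh,
        K_PEEP=cfg.peep_valve.K_PEEP,
        smoothing_width=cfg.peep_valve.smoothing_width,
    ))
    measured = float("nan")
    ok = True
    if verify:
        res = run_to_periodic(new_cfg, tol_rel=1e-3, rtol=rtol)
        measured = float(res.pressures[-1, 4])  # end of the final cycle
        ok = abs(measured - target_PEEP2) <= tol
    return new_cfg, PEEPTuning(p_thresh, target_PEEP2, measured, ok)
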
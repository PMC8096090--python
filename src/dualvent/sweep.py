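"""Parametric study of exhalation time constants.

Patient 1 is the anchor (DP1 = 15 cmH2O, R1 = 5 cmH2O/(L/s), C1 = 35
mL/cmH2O); patient 2's mechanics (R2, C2) and the ventilation ratios
DP2/DP1 and PEEP2/PEEP1 span grids.  At every grid point the pinch valves
are tuned to the driving-pressure targets, the in-line threshold is set
for the PEEP target, the circuit is run to periodic steady state, and each
patient's expiration is fitted with a single exponential.  The output
table is indexed by the five nondimensional ratios governing the coupled
discharge.

Rows whose driving-pressure target exceeds what the ventilator plateau can
deliver are flagged ``untunable`` (pinch valves only add restriction) but
are still simulated and fitted at the maximum achievable driving pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import LocalLoss, LungModel
from .errors import DualVentError, TuningError
from .metrics import patient_metrics
from .network import CircuitConfig
from .simulate import run_to_periodic
from .tuning import tune_peep_threshold, tune_pinch_valves


@dataclass
class SweepSpec:
    """Grids for the parametric study (anchors fixed to patient 1).

    Compliances are entered in mL/cmH2O (clinical convention) and
    converted internally.
    """

    base: CircuitConfig = field(default_factory=CircuitConfig)
    R1: float = 5.0  # cmH2O/(L/s)
    C1_mL: float = 35.0  # mL/cmH2O
    DP1: float = 15.0  # cmH2O
    R2_grid: tuple[float, ...] = (2.0, 5.0, 8.0)
    C2_grid_mL: tuple[float, ...] = (27.5, 35.0, 42.5)
    dp_ratios: tuple[float, ...] = (0.75, 1.0, 1.5)
    peep_ratios: tuple[float, ...] = (1.0, 1.5, 2.0)
    dp_tol: float = 0.1  # cmH2O
    rtol: float = 1e-3

    def ratio_bounds(self) -> dict[str, float]:
        """Printed-grid arithmetic: extreme ratios and the baseline
        exhalation-valve ratio."""
        return {
            "R2_R1_min": min(self.R2_grid) / self.R1,
            "R2_R1_max": max(self.R2_grid) / self.R1,
            "C2_C1_min": min(self.C2_grid_mL) / self.C1_mL,
            "C2_C1_max": max(self.C2_grid_mL) / self.C1_mL,
            "RV_R1": self.base.exhalation_valve.R_V / self.R1,
        }


def _point_config(spec: SweepSpec, R2: float, C2_mL: float) -> CircuitConfig:
    return spec.base.with_(
        lung1=LungModel(C_law=spec.C1_mL * 1e-3, R_law=spec.R1),
        lung2=LungModel(C_law=C2_mL * 1e-3, R_law=R2),
    )


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Run the full grid and return the tau-star table.

    One row per (R2, C2, DP-ratio, PEEP-ratio) combination with the five
    nondimensional ratios, fitted time constants, tau*, auto-PEEP flags,
    fit R^2, achieved driving pressures, and a status column (``ok`` /
    ``untunable`` / ``failed: ...``).  Asymmetry coefficients
    ``tau*/tau*_ref - 1`` are joined against the equal-driving-pressure
    rows afterwards.  Execution order does not affect the results (tuning
    warm starts only change iteration counts, not converged values).
    """
    rows = []
    peep1 = spec.base.ventilator.PEEP
    for peep_ratio in spec.peep_ratios:
        target_peep2 = peep_ratio * peep1
        cfg_peep, _ = tune_peep_threshold(spec.base, target_peep2, verify=False)
        for dp_ratio in spec.dp_ratios:
            targets = (spec.DP1, dp_ratio * spec.DP1)
            k_init = (0.0, 0.0)
            for R2 in spec.R2_grid:
                for C2 in spec.C2_grid_mL:
                    cfg = _point_config(spec, R2, C2).with_(
                        peep_valve=cfg_peep.peep_valve
                    )
                    row = {
                        "R2": R2,
                        "C2_mL": C2,
                        "dp_ratio": dp_ratio,
                        "peep_ratio": peep_ratio,
                        "R2_R1": R2 / spec.R1,
                        "C2_C1": C2 / spec.C1_mL,
                        "RV_R1": spec.base.exhalation_valve.R_V / spec.R1,
                        "P_thresh": cfg.peep_valve.P_thresh,
                    }
                    try:
                        res, status, k_used, dps = _tuned_run(
                            cfg, targets, spec, k_init
                        )
                        k_init = k_used
                        row.update(
                            {
                                "status": status,
                                "K_pinch1": k_used[0],
                                "K_pinch2": k_used[1],
                                "DP1_achieved": dps[0],
                                "DP2_achieved": dps[1],
                            }
                        )
                        for pat in (1, 2):
                            fit, ts = patient_metrics(res, pat)
                            row[f"tau{pat}"] = fit.tau
                            row[f"tau_star{pat}"] = ts.tau_star
                            row[f"autopeep{pat}"] = ts.autopeep
                            row[f"r2_{pat}"] = fit.r2
                        row["VT1"] = float(res.cycles.iloc[-1].VT1)
                        row["VT2"] = float(res.cycles.iloc[-1].VT2)
                        row["EEV1"] = float(res.cycles.iloc[-1].EEV1)
                        row["EEV2"] = float(res.cycles.iloc[-1].EEV2)
                    except DualVentError as exc:  # record, do not abort
                        row["status"] = f"failed: {exc}"
                    rows.append(row)
                    if progress:
                        print(
                            f"peep_ratio={peep_ratio} dp_ratio={dp_ratio} "
                            f"R2={R2} C2={C2}: {row.get('status')}"
                        )
    table = pd.DataFrame(rows)
    return _join_asymmetry(table)


def _tuned_run(cfg, targets, spec, k_init):
    """Pinch-tune one grid point; fall back to maximum achievable DP."""
    try:
        tuning = tune_pinch_valves(
            cfg, targets, tol=spec.dp_tol, K_init=k_init, rtol=spec.rtol
        )
        return tuning.result, "ok", tuning.K, tuning.achieved_DP
    except TuningError:
        # target beyond the plateau: open the valves fully and take what
        # the circuit gives
        open_cfg = cfg.with_(pinch1=LocalLoss(0.0), pinch2=LocalLoss(0.0))
        res = run_to_periodic(open_cfg, tol_rel=1e-3, rtol=spec.rtol)
        from .tuning import measured_dp

        return res, "untunable", (0.0, 0.0), measured_dp(res)


def _join_asymmetry(table: pd.DataFrame) -> pd.DataFrame:
    ref = table[table.dp_ratio == 1.0]
    if ref.empty:
        table["asym1"] = np.nan
        table["asym2"] = np.nan
        return table
    key = ["R2", "C2_mL", "peep_ratio"]
    ref = ref.set_index(key)
    for pat in (1, 2):
        col = f"tau_star{pat}"
        if col not in table.columns:
            table[f"asym{pat}"] = np.nan
            continue
        refs = table.apply(
            lambda r: ref[col].get((r["R2"], r["C2_mL"], r["peep_ratio"]), np.nan),
            axis=1,
        )
        table[f"asym{pat}"] = table[col] / refs - 1.0
    return table


def rv_sensitivity(
    spec: SweepSpec, rv_grid=(0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
) -> pd.DataFrame:
    """tau*(R_V) for identical patients under identical ventilation, with
    the analytic shared/(individual) references overlaid.

    The pinch valves are tuned once (the exhalation valve only carries
    expiratory flow, so inspiration — and hence DP — is unaffected by R_V).
    """
    from .components import ExhalationValve

    base = _point_config(spec, spec.R1, spec.C1_mL)
    tuning = tune_pinch_valves(base, (spec.DP1, spec.DP1), tol=spec.dp_tol)
    s = base.ventilator
    rows = []
    state = None
    for rv in rv_grid:
        cfg = base.with_(
            exhalation_valve=ExhalationValve(R_V=rv),
            pinch1=LocalLoss(tuning.K[0]),
            pinch2=LocalLoss(tuning.K[1]),
        )
        res = run_to_periodic(cfg, tol_rel=1e-3, rtol=spec.rtol, init_state=state)
        state = res.final_state
        _, ts1 = patient_metrics(res, 1)
        _, ts2 = patient_metrics(res, 2)
        rc = spec.C1_mL * 1e-3
        rows.append(
            {
                "R_V": rv,
                "tau_star1": ts1.tau_star,
                "tau_star2": ts2.tau_star,
                "tau_star_shared_ref": 4.0 * (spec.R1 + 2 * rv) * rc / s.t_ex,
                "tau_star_individual_ref": 4.0 * (spec.R1 + rv) * rc / s.t_ex,
            }
        )
    return pd.DataFrame(rows)


def kpeep_sensitivity(
    spec: SweepSpec,
    kpeep_grid_per_lmin2=(0.0, 3e-4, 6e-4, 1.24e-3, 2.5e-3, 5e-3),
) -> pd.DataFrame:
    """tau*(K_PEEP) for identical patients at fixed R_V.

    Patient 2 (the threshold-valve branch) slows down as the valve loss
    grows; patient 1 stays nearly constant.  ``K_PEEP = 0`` restores full
    symmetry.
    """
    from .components import PEEPValve

    base = _point_config(spec, spec.R1, spec.C1_mL)
    tuning = tune_pinch_valves(base, (spec.DP1, spec.DP1), tol=spec.dp_tol)
    rows = []
    state = None
    for k in kpeep_grid_per_lmin2:
        cfg = base.with_(
            pinch1=LocalLoss(tuning.K[0]),
            pinch2=LocalLoss(tuning.K[1]),
            peep_valve=PEEPValve(
                P_thresh=0.0,
                K_PEEP=LocalLoss.from_tagged(k, "cmH2O/(L/min)^2"),
            ),
        )
        res = run_to_periodic(cfg, tol_rel=1e-3, rtol=spec.rtol, init_state=state)
        state = res.final_state
        _, ts1 = patient_metrics(res, 1)
        _, ts2 = patient_metrics(res, 2)
        rows.append(
            {"K_PEEP_per_lmin2": k, "tau_star1": ts1.tau_star, "tau_star2": ts2.tau_star}
        )
    return pd.DataFrame(rows)


def autopeep_boundary(
    table: pd.DataFrame,
    patient: int,
    dp_ratio: float,
    peep_ratio: float,
) -> np.ndarray:
    """Linear-interpolated ``tau* = 1`` level set in the (R2/R1, C2/C1)
    plane for one panel; empty array when tau* never crosses 1.

    Crossing points are found on every grid edge (both axis directions)
    where tau*-1 changes sign.
    """
    sub = table[
        (table.dp_ratio == dp_ratio) & (table.peep_ratio == peep_ratio)
    ].dropna(subset=[f"tau_star{patient}"])
    if sub.empty:
        return np.empty((0, 2))
    xs = np.sort(sub["R2_R1"].unique())
    ys = np.sort(sub["C2_C1"].unique())
    z = np.full((len(xs), len(ys)), np.nan)
    for _, r in sub.iterrows():
        z[np.searchsorted(xs, r["R2_R1"]), np.searchsorted(ys, r["C2_C1"])] = (
            r[f"tau_star{patient}"] - 1.0
        )
    pts = []
    for i in range(len(xs)):
        for j in range(len(ys)):
            if np.isnan(z[i, j]):
                continue
            if i + 1 < len(xs) and not np.isnan(z[i + 1, j]) and z[i, j] * z[i + 1, j] < 0:
                f = z[i, j] / (z[i, j] - z[i + 1, j])
                pts.append((xs[i] + f * (xs[i + 1] - xs[i]), ys[j]))
            if j + 1 < len(ys) and not np.isnan(z[i, j + 1]) and z[i, j] * z[i, j + 1] < 0:
                f = z[i, j] / (z[i, j] - z[i, j + 1])
                pts.append((xs[i], ys[j] + f * (ys[j + 1] - ys[j])))
            if z[i, j] == 0.0:
                pts.append((xs[i], ys[j]))
    return np.array(pts) if pts else np.empty((0, 2))
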
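"""Run-configuration schema and YAML parsing.

A run config is a YAML mapping with blocks ``ventilator``, ``circuit``,
``patients``, ``solver`` and an optional ``seed``.  Unknown keys are
rejected.  Fixed unit conventions (documented per key below) apply, with
one exception: localized loss coefficients are quoted in vendor units per
(L/min)^2 as often as per (L/s)^2, so every ``K_*`` entry must carry an
explicit unit tag — either ``{value: .., unit: ..}`` or a ``"VALUE UNIT"``
string.

Units by key:
  ventilator.BR [1/min], t_ins/rise_time/fall_* [s], PEEP/P_max [cmH2O],
  R_V [cmH2O/(L/s)]
  circuit.tubes.*.L/D/eps [m], dVdP [mL/cmH2O]
  circuit.K_oneway / K_filter / K_PEEP / K_pinch* [tagged]
  circuit.peep_thresh [cmH2O]
  patients[i].R [cmH2O/(L/s)], C [mL/cmH2O], PEEP [cmH2O], DP [cmH2O]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .components import (
    ExhalationValve,
    LocalLoss,
    LungModel,
    PEEPValve,
    TubeSegment,
)
from .errors import ConfigError
from .linear import LinearConfig, LinearPatient
from .network import CircuitConfig, default_tubes
from .waveform import VentilatorSettings

_VENT_KEYS = {
    "BR", "t_ins", "PEEP", "P_max", "rise_time", "overshoot_frac",
    "fall_midpoint", "fall_steepness", "R_V",
}
_CIRCUIT_KEYS = {
    "tubes", "K_oneway", "K_filter", "K_PEEP", "K_pinch1", "K_pinch2",
    "peep_thresh", "short_circuit", "rigid_tubes",
}
_TUBE_KEYS = {"L", "D", "eps", "dVdP"}
_PATIENT_KEYS = {"R", "C", "PEEP", "DP", "C_table", "R_table"}
_SOLVER_KEYS = {"rtol", "max_cycles", "samples_per_cycle", "tol_rel"}
_TOP_KEYS = {"ventilator", "circuit", "patients", "solver", "seed"}


@dataclass
class SolverSettings:
    rtol: float = 1e-3
    max_cycles: int = 50
    samples_per_cycle: int = 300
    tol_rel: float = 1e-3


@dataclass
class RunConfig:
    """Parsed, unit-converted configuration plus provenance extras."""

    circuit: CircuitConfig
    solver: SolverSettings = field(default_factory=SolverSettings)
    seed: int = 0
    raw: dict = field(default_factory=dict)
    target_DP: tuple[float, float] = (15.0, 15.0)

    def linear_config(self, DP=(15.0, 15.0)) -> LinearConfig:
        """Project the circuit onto the linear two-compartment model
        (constant laws only)."""
        c = self.circuit
        pats = []
        peeps = (c.peep1, c.peep2)
        for i, lung in enumerate((c.lung1, c.lung2)):
            if not isinstance(lung.C_law, (int, float)) or not isinstance(
                lung.R_law, (int, float)
            ):
                raise ConfigError("linear model requires constant lung laws")
            pats.append(
                LinearPatient(R=lung.R_law, C=lung.C_law, PEEP=peeps[i], DP=DP[i])
            )
        return LinearConfig(p1=pats[0], p2=pats[1], R_V=c.exhalation_valve.R_V)


def _check_keys(block: dict, allowed: set, where: str):
    if not isinstance(block, dict):
        raise ConfigError(f"{where} must be a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def _parse_k(entry, where: str) -> LocalLoss:
    """A loss coefficient must carry its unit tag."""
    if isinstance(entry, dict):
        if set(entry) != {"value", "unit"}:
            raise ConfigError(f"{where}: expected {{value, unit}}")
        return LocalLoss.from_tagged(float(entry["value"]), str(entry["unit"]))
    if isinstance(entry, str):
        parts = entry.split(None, 1)
        if len(parts) != 2:
            raise ConfigError(f"{where}: expected 'VALUE UNIT' string")
        try:
            value = float(parts[0])
        except ValueError as exc:
            raise ConfigError(f"{where}: bad numeric value {parts[0]!r}") from exc
        return LocalLoss.from_tagged(value, parts[1].strip())
    raise ConfigError(
        f"{where}: loss coefficients need an explicit unit tag "
        "({value, unit} mapping or 'VALUE UNIT' string)"
    )


def _load_table(entry, where: str):
    """A law table: inline list of [x, y] rows, or a path to a
    two-column headerless/commented CSV."""
    import numpy as np

    if isinstance(entry, (str, Path)):
        import pandas as pd

        path = Path(entry)
        if not path.exists():
            raise ConfigError(f"{where}: table file not found: {path}")
        arr = pd.read_csv(path, comment="#", header=None).to_numpy(dtype=float)
    else:
        arr = np.asarray(entry, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ConfigError(f"{where}: expected two columns")
    return arr.T


def _parse_lung(block: dict, where: str) -> tuple[LungModel, float, float]:
    _check_keys(block, _PATIENT_KEYS, where)
    c_law = block.get("C_table")
    if c_law is not None:
        # table given as (V [mL], C [mL/cmH2O])
        v, c = _load_table(c_law, f"{where}.C_table")
        c_law = (v * 1e-3, c * 1e-3)
    else:
        c_law = float(block.get("C", 35.0)) * 1e-3  # mL/cmH2O -> L/cmH2O
    r_law = block.get("R_table")
    if r_law is not None:
        # table given as (q [L/s], R [cmH2O/(L/s)])
        q, r = _load_table(r_law, f"{where}.R_table")
        r_law = (q, r)
    else:
        r_law = float(block.get("R", 5.0))
    lung = LungModel(C_law=c_law, R_law=r_law)
    return lung, float(block.get("PEEP", 5.0)), float(block.get("DP", 15.0))


def parse_config(data: dict) -> RunConfig:
    """Validate and unit-convert a configuration mapping."""
    if data is None:
        data = {}
    _check_keys(data, _TOP_KEYS, "config")

    vent_block = dict(data.get("ventilator", {}))
    _check_keys(vent_block, _VENT_KEYS, "ventilator")
    r_v = float(vent_block.pop("R_V", 1.5))
    vent = VentilatorSettings(**{k: float(v) for k, v in vent_block.items()})

    circ = dict(data.get("circuit", {}))
    _check_keys(circ, _CIRCUIT_KEYS, "circuit")
    tubes = default_tubes()
    for name, tb in dict(circ.get("tubes", {})).items():
        if name not in tubes:
            raise ConfigError(f"unknown tube segment {name!r}")
        _check_keys(tb, _TUBE_KEYS, f"circuit.tubes.{name}")
        kw = {k: float(v) for k, v in tb.items()}
        if "dVdP" in kw:
            kw["dVdP"] = kw["dVdP"] * 1e-3  # mL/cmH2O -> L/cmH2O
        base = tubes[name]
        tubes[name] = TubeSegment(
            L=kw.get("L", base.L),
            D=kw.get("D", base.D),
            eps=kw.get("eps", base.eps),
            dVdP=kw.get("dVdP", base.dVdP),
        )

    losses = {}
    for key, default in (
        ("K_oneway", LocalLoss.from_tagged(9.01e-4, "cmH2O/(L/min)^2")),
        ("K_filter", LocalLoss.from_tagged(4.80e-4, "cmH2O/(L/min)^2")),
        ("K_PEEP", LocalLoss.from_tagged(1.24e-3, "cmH2O/(L/min)^2")),
        ("K_pinch1", LocalLoss(0.0)),
        ("K_pinch2", LocalLoss(0.0)),
    ):
        losses[key] = _parse_k(circ[key], f"circuit.{key}") if key in circ else default

    patients = data.get("patients", [{}, {}])
    if not isinstance(patients, list) or len(patients) != 2:
        raise ConfigError("patients must be a list of exactly two mappings")
    lung1, peep1, dp1 = _parse_lung(dict(patients[0]), "patients[0]")
    lung2, peep2, dp2 = _parse_lung(dict(patients[1]), "patients[1]")
    if abs(peep1 - vent.PEEP) > 1e-9:
        # patient 1 has no threshold valve; their PEEP is the ventilator's
        vent = VentilatorSettings(
            BR=vent.BR, t_ins=vent.t_ins, PEEP=peep1, P_max=vent.P_max,
            rise_time=vent.rise_time, overshoot_frac=vent.overshoot_frac,
            fall_midpoint=vent.fall_midpoint, fall_steepness=vent.fall_steepness,
        )
    peep_thresh = float(circ.get("peep_thresh", max(0.0, peep2 - peep1)))

    circuit = CircuitConfig(
        ventilator=vent,
        exhalation_valve=ExhalationValve(R_V=r_v),
        tubes=tubes,
        oneway=losses["K_oneway"],
        filter=losses["K_filter"],
        pinch1=losses["K_pinch1"],
        pinch2=losses["K_pinch2"],
        peep_valve=PEEPValve(P_thresh=peep_thresh, K_PEEP=losses["K_PEEP"]),
        lung1=lung1,
        lung2=lung2,
        short_circuit=bool(circ.get("short_circuit", True)),
        rigid_tubes=bool(circ.get("rigid_tubes", False)),
    )

    solver_block = dict(data.get("solver", {}))
    _check_keys(solver_block, _SOLVER_KEYS, "solver")
    solver = SolverSettings(
        rtol=float(solver_block.get("rtol", 1e-3)),
        max_cycles=int(solver_block.get("max_cycles", 50)),
        samples_per_cycle=int(solver_block.get("samples_per_cycle", 300)),
        tol_rel=float(solver_block.get("tol_rel", 1e-3)),
    )
    return RunConfig(
        circuit=circuit,
        solver=solver,
        seed=int(data.get("seed", 0)),
        raw=data,
        target_DP=(dp1, dp2),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data)


def resolved_dict(rc: RunConfig) -> dict:
    """Echo of the fully resolved configuration (canonical units) for
    provenance output."""
    c = rc.circuit
    v = c.ventilator
    return {
        "ventilator": {
            "BR": v.BR, "t_ins": v.t_ins, "PEEP": v.PEEP, "P_max": v.P_max,
            "rise_time": v.rise_time, "overshoot_frac": v.overshoot_frac,
            "fall_midpoint": v.fall_midpoint, "fall_steepness": v.fall_steepness,
            "R_V": c.exhalation_valve.R_V,
        },
        "circuit": {
            "tubes": {
                n: {"L": t.L, "D": t.D, "eps": t.eps, "dVdP_L_per_cmH2O": t.wall_compliance}
                for n, t in c.tubes.items()
            },
            "K_oneway_per_ls2": c.oneway.K,
            "K_filter_per_ls2": c.filter.K,
            "K_PEEP_per_ls2": c.peep_valve.K_PEEP.K,
            "K_pinch_per_ls2": [c.pinch1.K, c.pinch2.K],
            "peep_thresh": c.peep_valve.P_thresh,
            "short_circuit": c.short_circuit,
            "rigid_tubes": c.rigid_tubes,
        },
        "patients": [
            {
                "R": c.lung1.R_law if isinstance(c.lung1.R_law, float) else "table",
                "C_L_per_cmH2O": c.lung1.C_law if isinstance(c.lung1.C_law, float) else "table",
                "PEEP": c.peep1,
            },
            {
                "R": c.lung2.R_law if isinstance(c.lung2.R_law, float) else "table",
                "C_L_per_cmH2O": c.lung2.C_law if isinstance(c.lung2.C_law, float) else "table",
                "PEEP": c.peep2,
            },
        ],
        "solver": {
            "rtol": rc.solver.rtol,
            "max_cycles": rc.solver.max_cycles,
            "samples_per_cycle": rc.solver.samples_per_cycle,
            "tol_rel": rc.solver.tol_rel,
        },
        "seed": rc.seed,
    }
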
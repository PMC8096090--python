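"""Network assembly: configuration -> flat parameter arrays for the kernel.

Topology (single-line scheme of the shared-ventilation circuit):

::

    src ==[cv]==[vent_insp]== (SPLIT) ==[ow+pinch]==[tube]== (AW1) --lung1
                                 |  \\__[ow+pinch]==[tube]== (AW2) --lung2
                           [short circuit]                    |      |
                                 |   __[tube]==[filter+ow]____/      |
    src ==[cv+R_V]==[vent_exp]==(MERGE)==[tube]==[filter+ow+PEEPvalve]

Capacitive nodes: inspiratory split, expiratory merge, and the two patient
airway openings; each aggregates the wall compliance of its adjacent tube
halves.  Both pressure sources carry the same composite waveform — phase
switching is done by the check valves, not by reconfiguring the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .components import (
    CMH2O_PA,
    CheckValve,
    ExhalationValve,
    LocalLoss,
    LungModel,
    PEEPValve,
    TubeSegment,
)
from .errors import ConfigError
from .waveform import VentilatorSettings

#: floor on a node's aggregated compliance [L/cmH2O]; "rigid" tubes keep a
#: vanishingly small storage so node pressures remain differential states
RIGID_NODE_COMPLIANCE = 2.0e-5


def default_tubes() -> dict[str, TubeSegment]:
    """Standard circuit geometry: 1 m x 20 mm limbs, 15 cm x 4 mm short
    circuit."""
    std = dict(L=1.0, D=0.020)
    return {
        "vent_insp": TubeSegment(**std),
        "vent_exp": TubeSegment(**std),
        "short_circuit": TubeSegment(L=0.15, D=0.004),
        "patient1_insp": TubeSegment(**std),
        "patient1_exp": TubeSegment(**std),
        "patient2_insp": TubeSegment(**std),
        "patient2_exp": TubeSegment(**std),
    }


TUBE_NAMES = tuple(default_tubes().keys())

BRANCH_NAMES = (
    "insp_source",
    "exp_source",
    "short_circuit",
    "patient1_insp",
    "patient2_insp",
    "patient1_exp",
    "patient2_exp",
)

CAPACITIVE_NODES = ("insp_split", "exp_merge", "airway1", "airway2")


@dataclass(frozen=True)
class CircuitConfig:
    """Full description of the ventilator-splitter-two-patient network.

    Loss coefficients are canonical cmH2O/(L/s)^2 (use
    ``LocalLoss.from_tagged`` for vendor units).  ``peep_valve.P_thresh``
    raises patient 2's PEEP above the ventilator's by that amount.
    """

    ventilator: VentilatorSettings = field(default_factory=VentilatorSettings)
    exhalation_valve: ExhalationValve = field(default_factory=ExhalationValve)
    tubes: dict[str, TubeSegment] = field(default_factory=default_tubes)
    oneway: LocalLoss = field(
        default_factory=lambda: LocalLoss.from_tagged(9.01e-4, "cmH2O/(L/min)^2")
    )
    filter: LocalLoss = field(
        default_factory=lambda: LocalLoss.from_tagged(4.80e-4, "cmH2O/(L/min)^2")
    )
    pinch1: LocalLoss = field(default_factory=lambda: LocalLoss(0.0))
    pinch2: LocalLoss = field(default_factory=lambda: LocalLoss(0.0))
    peep_valve: PEEPValve = field(default_factory=PEEPValve)
    lung1: LungModel = field(default_factory=LungModel)
    lung2: LungModel = field(default_factory=LungModel)
    check_valve: CheckValve = field(default_factory=CheckValve)
    short_circuit: bool = True
    rigid_tubes: bool = False
    ideal_tubes: bool = False
    detach_patient2: bool = False

    def __post_init__(self):
        missing = set(TUBE_NAMES) - set(self.tubes)
        if missing:
            raise ConfigError(f"missing tube segments: {sorted(missing)}")
        extra = set(self.tubes) - set(TUBE_NAMES)
        if extra:
            raise ConfigError(f"unknown tube segments: {sorted(extra)}")

    # -- convenience -------------------------------------------------------
    @property
    def peep1(self) -> float:
        """Nominal PEEP of patient 1 (the ventilator's) [cmH2O]."""
        return self.ventilator.PEEP

    @property
    def peep2(self) -> float:
        """Nominal PEEP of patient 2: ventilator PEEP plus the in-line
        threshold [cmH2O]."""
        return self.ventilator.PEEP + self.peep_valve.P_thresh

    def with_(self, **kw) -> "CircuitConfig":
        """Functional update (frozen dataclass)."""
        return replace(self, **kw)


class Network:
    """Assembled network: parameter arrays plus callable RHS/observables."""

    def __init__(self, cfg: CircuitConfig):
        self.cfg = cfg
        self.p = np.zeros(K.NPARAM)
        self.qwork = np.zeros(K.NBRANCH)
        self._obs_scratch = np.empty(K.NOBS)
        self._pack(cfg)
        self.lung_arrays = tuple(
            arr for lung in (cfg.lung1, cfg.lung2) for arr in _lung_tables(lung)
        )
        self.branch_names = BRANCH_NAMES
        self.capacitive_nodes = CAPACITIVE_NODES
        self.n_lungs = 2

    # -- assembly ----------------------------------------------------------
    def _pack(self, cfg: CircuitConfig):
        p = self.p
        s = cfg.ventilator
        zeta, omega = s.damping()
        p[K.IV_PERIOD] = s.period
        p[K.IV_TINS] = s.t_ins
        p[K.IV_PEEP] = s.PEEP
        p[K.IV_PMAX] = s.P_max
        p[K.IV_ZETA] = zeta
        p[K.IV_OMEGA] = omega
        p[K.IV_FMID] = s.fall_midpoint
        p[K.IV_FK] = s.fall_steepness
        p[K.IV_CRIT] = 1.0 if zeta >= 1.0 else 0.0
        p[K.IV_DETACH2] = 1.0 if cfg.detach_patient2 else 0.0

        t = cfg.tubes
        w = cfg.check_valve.smoothing_width
        ow = cfg.oneway.K
        filt = cfg.filter.K
        rows = [
            # (tube, K, Rlin, crack, width, oneway, enabled)
            (t["vent_insp"], 0.0, 0.0, cfg.check_valve.P_crack, w, 1.0, 1.0),
            (t["vent_exp"], 0.0, cfg.exhalation_valve.R_V, cfg.check_valve.P_crack, w, 1.0, 1.0),
            (t["short_circuit"], 0.0, 0.0, 0.0, w, 0.0, 1.0 if cfg.short_circuit else 0.0),
            (t["patient1_insp"], ow + cfg.pinch1.K, 0.0, cfg.check_valve.P_crack, w, 1.0, 1.0),
            (t["patient2_insp"], ow + cfg.pinch2.K, 0.0, cfg.check_valve.P_crack, w, 1.0,
             0.0 if cfg.detach_patient2 else 1.0),
            (t["patient1_exp"], ow + filt, 0.0, cfg.check_valve.P_crack, w, 1.0, 1.0),
            (t["patient2_exp"], ow + filt + cfg.peep_valve.K_PEEP.K, 0.0,
             cfg.peep_valve.P_thresh + cfg.check_valve.P_crack,
             max(w, cfg.peep_valve.smoothing_width), 1.0,
             0.0 if cfg.detach_patient2 else 1.0),
        ]
        for b, (tube, kq, rlin, crack, width, oneway, enabled) in enumerate(rows):
            c_q2 = (tube.L / tube.D) * tube.rho / (2.0 * tube.area**2) * 1e-6 / CMH2O_PA
            recoef = tube.rho * tube.D * 1e-3 / (tube.area * tube.mu)
            if cfg.ideal_tubes:
                # linear-limit configuration: no pipe friction; keep a tiny
                # linear resistance so every branch law stays invertible
                c_q2 = 0.0
                rlin = max(rlin, 1e-2)
            i = K.BP0 + b * K.BPS
            p[i + K.B_CQ2] = c_q2
            p[i + K.B_CLAM] = 64.0 * c_q2 / recoef
            p[i + K.B_RECOEF] = recoef
            p[i + K.B_RR] = tube.eps / tube.D
            p[i + K.B_K] = kq
            p[i + K.B_RLIN] = rlin
            p[i + K.B_CRACK] = crack
            p[i + K.B_WIDTH] = width
            p[i + K.B_ONEWAY] = oneway
            p[i + K.B_ENABLED] = enabled

        # node compliances: half of each adjacent tube's wall compliance
        def half(name):
            if cfg.rigid_tubes or cfg.ideal_tubes:
                return 0.0
            return 0.5 * t[name].wall_compliance

        cn = [
            half("vent_insp") + half("patient1_insp") + half("patient2_insp") + (half("short_circuit") if cfg.short_circuit else 0.0),
            half("vent_exp") + half("patient1_exp") + half("patient2_exp") + (half("short_circuit") if cfg.short_circuit else 0.0),
            half("patient1_insp") + half("patient1_exp"),
            half("patient2_insp") + half("patient2_exp"),
        ]
        for k, c in enumerate(cn):
            p[K.NC0 + k] = max(c, RIGID_NODE_COMPLIANCE)

    # -- evaluation --------------------------------------------------------
    @property
    def node_compliances(self) -> np.ndarray:
        return self.p[K.NC0:K.NC0 + 4].copy()

    def initial_state(self) -> np.ndarray:
        """Lungs at their nominal-PEEP volumes, nodes at ventilator PEEP."""
        cfg = self.cfg
        y = np.empty(6)
        y[0] = self.p[K.NC0 + 0] * cfg.peep1
        y[1] = self.p[K.NC0 + 1] * cfg.peep1
        y[2] = self.p[K.NC0 + 2] * cfg.peep1
        y[3] = self.p[K.NC0 + 3] * cfg.peep2
        y[4] = cfg.lung1.volume_at_pressure(cfg.peep1)
        y[5] = cfg.lung2.volume_at_pressure(cfg.peep2)
        return y

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return K.rhs(t, y, self.p, *self.lung_arrays, self.qwork, self._obs_scratch)

    def observe(self, t: float, y: np.ndarray) -> np.ndarray:
        """[P_src, P_split, P_merge, P_aw1, P_aw2, q(7 branches), q_lung1,
        q_lung2] at one instant."""
        return K.observe(t, y, self.p, *self.lung_arrays, self.qwork.copy())

    def describe(self) -> dict:
        """Construction summary used by tests and run provenance."""
        enabled = [
            name
            for b, name in enumerate(BRANCH_NAMES)
            if self.p[K.BP0 + b * K.BPS + K.B_ENABLED] > 0.5
        ]
        return {
            "branches": list(BRANCH_NAMES),
            "enabled_branches": enabled,
            "capacitive_nodes": list(CAPACITIVE_NODES),
            "n_lungs": self.n_lungs,
            "node_compliances": self.node_compliances.tolist(),
        }


def _lung_tables(lung: LungModel):
    if isinstance(lung.C_law, (int, float)):
        vg, cv = np.array([0.0]), np.array([float(lung.C_law)])
    else:
        vg, cv = (np.asarray(a, dtype=float) for a in lung.C_law)
    if isinstance(lung.R_law, (int, float)):
        qg, rv = np.array([0.0]), np.array([float(lung.R_law)])
    else:
        qg, rv = (np.asarray(a, dtype=float) for a in lung.R_law)
    return vg, cv, qg, rv


def assemble_network(cfg: CircuitConfig) -> Network:
    """Build the runnable network for a configuration.

    Raises :class:`ConfigError` for inconsistent configurations (missing
    tubes, a second PEEP valve is impossible by construction — the topology
    fixes exactly one, on patient 2's expiratory branch).
    """
    return Network(cfg)
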
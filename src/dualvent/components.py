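"""Constitutive laws of the hydraulic network elements.

Every element maps a flow to a pressure drop (or, for storage elements, a
pressure to a stored volume).  All laws pass through the origin, are odd or
one-sided-zero, and dissipate (dP*q >= 0), which is what keeps the
assembled network integrable.

Internal units: pressure cmH2O, flow L/s, volume L, geometry SI.  Localised
loss coefficients ``K`` are canonically cmH2O/(L/s)^2; vendor tables quoted
per (L/min)^2 are converted by the factor 3600 at parse time.

These pure-Python implementations are the reference semantics; the ODE
right-hand side re-implements the same formulas inside a compiled kernel
(see ``_kernels``), and the test suite cross-checks the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError

#: 1 cmH2O in Pa
CMH2O_PA = 98.0665

#: conversion factor for K given per (L/min)^2 -> per (L/s)^2
K_PER_LMIN2_TO_PER_LS2 = 3600.0

#: allowed unit tags for localized loss coefficients
K_UNITS = {
    "cmH2O/(L/min)^2": K_PER_LMIN2_TO_PER_LS2,
    "cmH2O/(L/s)^2": 1.0,
}


# ---------------------------------------------------------------------------
# tubes

@dataclass(frozen=True)
class TubeSegment:
    """A lumped tube: Darcy-Weisbach friction plus elastic wall storage.

    ``dVdP`` is the wall compliance in L/cmH2O for the whole segment; the
    default is the typical breathing-circuit value of 1 mL/cmH2O per metre
    of tube.  (The static pressure-diameter coefficient is derivable from
    it but is not an input — the volumetric compliance is the quantity that
    matters for the lumped network.)
    """

    L: float  # length [m]
    D: float  # internal diameter [m]
    eps: float = 2.0e-4  # wall roughness [m]
    dVdP: float | None = None  # wall compliance [L/cmH2O]; None -> 1 mL/cmH2O per m
    rho: float = 1.2  # gas density [kg/m^3], air at ~20 C
    mu: float = 1.81e-5  # dynamic viscosity [Pa s]

    def __post_init__(self):
        if self.L <= 0 or self.D <= 0:
            raise ConfigError("tube L and D must be positive")
        if self.eps < 0:
            raise ConfigError("tube roughness must be non-negative")

    @property
    def area(self) -> float:
        return math.pi * self.D**2 / 4.0

    @property
    def wall_compliance(self) -> float:
        """dV/dP [L/cmH2O] (default 1 mL/cmH2O per metre)."""
        if self.dVdP is not None:
            return self.dVdP
        return 1.0e-3 * self.L

    @property
    def dDdP(self) -> float:
        """Static pressure-diameter coefficient [m/Pa] implied by dV/dP,
        from dV/dP = L*pi*D/2 * dD/dP (thin-walled circular pipe)."""
        dvdp_si = self.wall_compliance * 1e-3 / CMH2O_PA  # m^3/Pa
        return dvdp_si / (self.L * math.pi * self.D / 2.0)


def friction_factor(Re: float, rel_rough: float = 0.0) -> float:
    """Darcy friction factor f(Re, eps/D).

    Laminar ``64/Re`` below Re=2000, the explicit Haaland correlation above
    Re=4000, and a linear blend in between (the transitional regime is not
    otherwise specified; continuity keeps the solver happy).  ``Re=0`` is
    not meaningful here — the laminar limit is taken analytically inside
    :func:`tube_dp`, where ``f*q^2`` collapses to a linear law.
    """
    if Re < 0:
        raise ConfigError("Reynolds number must be non-negative")
    if Re == 0:
        raise ConfigError("friction_factor undefined at Re=0; use tube_dp")
    if Re < 2000.0:
        return 64.0 / Re
    f4 = _haaland(4000.0, rel_rough)
    if Re >= 4000.0:
        return _haaland(Re, rel_rough)
    f2 = 64.0 / 2000.0
    return f2 + (f4 - f2) * (Re - 2000.0) / 2000.0


def _haaland(Re: float, rel_rough: float) -> float:
    inv_sqrt = -1.8 * math.log10((rel_rough / 3.7) ** 1.11 + 6.9 / Re)
    return 1.0 / inv_sqrt**2


def reynolds(tube: TubeSegment, q: float) -> float:
    """Reynolds number for a flow of ``q`` L/s."""
    return tube.rho * tube.D * abs(q) * 1e-3 / (tube.area * tube.mu)


def tube_dp(tube: TubeSegment, q: float) -> float:
    """Darcy pressure drop [cmH2O] for flow ``q`` [L/s]; odd in ``q``.

    ``dP = f(Re, eps/D) * (L/D) * rho/(2 A^2) * q|q|``.  In the laminar
    regime the product ``f*q^2`` reduces exactly to the Hagen-Poiseuille
    linear law ``128 mu L q / (pi D^4)``, so the law is smooth through zero
    flow.
    """
    if q == 0.0:
        return 0.0
    re = reynolds(tube, q)
    c_q2 = (tube.L / tube.D) * tube.rho / (2.0 * tube.area**2) * 1e-6 / CMH2O_PA
    if re < 2000.0:
        # analytic laminar limit: (64/Re) * c_q2 * q^2 is linear in q
        c_lam = 64.0 * c_q2 / (tube.rho * tube.D * 1e-3 / (tube.area * tube.mu))
        return c_lam * q
    return friction_factor(re, tube.eps / tube.D) * c_q2 * q * abs(q)


def tube_stored_volume(tube: TubeSegment, P: float) -> float:
    """Volume stored in the elastic wall at gauge pressure ``P`` [L]."""
    return tube.wall_compliance * P


# ---------------------------------------------------------------------------
# localized losses and valves

@dataclass(frozen=True)
class LocalLoss:
    """Quadratic localized loss ``dP = K q|q|``; K in cmH2O/(L/s)^2."""

    K: float

    def __post_init__(self):
        if self.K < 0:
            raise ConfigError("loss coefficient K must be non-negative")

    @classmethod
    def from_tagged(cls, value: float, unit: str) -> "LocalLoss":
        """Build from a value with an explicit unit tag (required in config
        files, where vendor tables are usually per (L/min)^2)."""
        if unit not in K_UNITS:
            raise ConfigError(
                f"unknown loss-coefficient unit {unit!r}; expected one of {sorted(K_UNITS)}"
            )
        return cls(K=value * K_UNITS[unit])


def local_dp(loss: LocalLoss, q: float) -> float:
    """Pressure drop across a localized loss [cmH2O]; odd in q."""
    return loss.K * q * abs(q)


@dataclass(frozen=True)
class CheckValve:
    """One-way valve with cracking pressure and a narrow C1 regularisation.

    Below ``P_crack`` the valve is shut.  An ideal diode would make the
    dynamics nonsmooth, so the effective driving pressure ramps in
    quadratically over ``smoothing_width`` (default 0.01 cmH2O) before
    becoming ``dp - P_crack - width/2`` — accurate away from the band,
    integrable inside it.
    """

    P_crack: float = 0.0
    smoothing_width: float = 0.01

    def __post_init__(self):
        if self.P_crack < 0:
            raise ConfigError("cracking pressure must be non-negative")
        if self.smoothing_width <= 0:
            raise ConfigError("smoothing width must be positive")

    def effective_dp(self, dp: float) -> float:
        """C1 monotone ramp of the post-crack driving pressure."""
        x = dp - self.P_crack
        w = self.smoothing_width
        if x <= 0.0:
            return 0.0
        if x < w:
            return 0.5 * x * x / w
        return x - 0.5 * w


def check_valve_q(
    valve: CheckValve,
    dp: float,
    series_law: Callable[[float], float],
    q_max: float = 10.0,
) -> float:
    """Flow [L/s] through a check valve feeding a series pressure-drop law.

    Zero for ``dp <= P_crack``; otherwise the unique ``q >= 0`` solving
    ``series_law(q) = effective_dp(dp)``.  ``series_law`` must be strictly
    increasing for q > 0.
    """
    dpe = valve.effective_dp(dp)
    if dpe <= 0.0:
        return 0.0
    hi = q_max
    f_hi = series_law(hi) - dpe
    tries = 0
    while f_hi < 0 and tries < 60:
        hi *= 2.0
        f_hi = series_law(hi) - dpe
        tries += 1
    if f_hi < 0:
        raise ConfigError("series_law does not reach the driving pressure; not increasing?")
    if series_law(0.0) != 0.0:
        raise ConfigError("series_law must vanish at q=0")
    return brentq(lambda q: series_law(q) - dpe, 0.0, hi, xtol=1e-12, rtol=1e-12)


@dataclass(frozen=True)
class PEEPValve:
    """In-line threshold valve: a check valve whose cracking pressure sets
    the extra PEEP, plus its own quadratic loss."""

    P_thresh: float = 0.0
    K_PEEP: LocalLoss = field(default_factory=lambda: LocalLoss.from_tagged(1.24e-3, "cmH2O/(L/min)^2"))
    smoothing_width: float = 0.01

    def __post_init__(self):
        if self.P_thresh < 0:
            raise ConfigError("PEEP-valve threshold must be non-negative")

    def as_check_valve(self) -> CheckValve:
        return CheckValve(P_crack=self.P_thresh, smoothing_width=self.smoothing_width)


@dataclass(frozen=True)
class ExhalationValve:
    """Ventilator exhalation valve, linearised: ``dP = R_V * q``."""

    R_V: float = 1.5

    def __post_init__(self):
        if self.R_V < 0:
            raise ConfigError("R_V must be non-negative")


# ---------------------------------------------------------------------------
# lungs

Law = Union[float, tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class LungModel:
    """Spring-damper-piston lung: elastic recoil plus resistive drop.

    ``C_law`` is the compliance [L/cmH2O], either a constant or a table
    ``(V [L], C [L/cmH2O])`` interpolated in volume; ``R_law`` is the
    resistance [cmH2O/(L/s)], constant or tabulated against |flow| [L/s].
    Airway-opening pressure is ``P = V/C(V) + R(qdot)*qdot`` with
    ``qdot > 0`` meaning inflow.
    """

    C_law: Law = 0.035
    R_law: Law = 5.0
    V0: float = 0.0  # relaxed volume offset [L]

    def __post_init__(self):
        for law, name in ((self.C_law, "C_law"), (self.R_law, "R_law")):
            if isinstance(law, (int, float)):
                if law <= 0:
                    raise ConfigError(f"{name} must be strictly positive")
            else:
                x, y = law
                if len(x) != len(y) or len(x) < 2:
                    raise ConfigError(f"{name} table needs >= 2 matching rows")
                if np.any(np.asarray(y) <= 0):
                    raise ConfigError(f"{name} must be strictly positive over its range")
                if np.any(np.diff(x) <= 0):
                    raise ConfigError(f"{name} table abscissa must be increasing")

    def compliance(self, V: float) -> float:
        if isinstance(self.C_law, (int, float)):
            return float(self.C_law)
        x, y = self.C_law
        if V < x[0] - 1e-12 or V > x[-1] + 1e-12:
            raise ConfigError(f"volume {V} outside tabulated compliance range")
        return float(np.interp(V, x, y))

    def resistance(self, qdot: float) -> float:
        if isinstance(self.R_law, (int, float)):
            return float(self.R_law)
        x, y = self.R_law
        return float(np.interp(abs(qdot), x, y))

    def volume_at_pressure(self, P: float) -> float:
        """Static volume with ``V/C(V) = P`` (fixed point for tabulated laws)."""
        if isinstance(self.C_law, (int, float)):
            return self.C_law * P
        v = float(self.C_law[1][0]) * P
        for _ in range(100):
            vn = self.compliance(min(max(v, self.C_law[0][0]), self.C_law[0][-1])) * P
            if abs(vn - v) < 1e-12:
                break
            v = 0.5 * (v + vn)
        return v


def lung_pressure(lung: LungModel, V: float, qdot: float) -> float:
    """Airway-opening pressure [cmH2O] at volume ``V`` [L], flow ``qdot``
    [L/s] (positive = inflow)."""
    if V < 0:
        raise ConfigError("lung volume must be non-negative")
    return V / lung.compliance(V) + lung.resistance(qdot) * qdot
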
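"""Closed-form linear two-compartment exhalation model.

During expiration, each patient is an RC compartment (airway resistance
``R_i``, lung compliance ``C_i``) discharging towards the ventilator PEEP
level through a shared exhalation-valve resistance ``R_V``.  Kirchhoff's
laws give a coupled pair of first-order ODEs for the lung volumes::

    V1/C1 + R1*dV1 + R_V*(dV1 + dV2) = PEEP1
    V2/C2 + R2*dV2 + R_V*(dV1 + dV2) = PEEP2

or in matrix form ``Cmat.V + Rmat.dV = peep`` with ``Cmat = diag(1/C1,
1/C2)`` and ``Rmat = [[R1+R_V, R_V], [R_V, R2+R_V]]``.  The homogeneous
solution is a sum of two decaying modes, ``V(t) = alpha*A1*exp(-t/lam1) +
beta*A2*exp(-t/lam2) + C_i*PEEP_i``, where ``lam1 >= lam2 > 0`` are the
eigenvalues (in seconds) of ``diag(C).Rmat`` and the amplitudes follow from
the end-inspiratory state, ``(DP1*C1, DP2*C2) = alpha*A1 + beta*A2``, under
the assumption of null flow at the end of inspiration.

The in-line PEEP valve on patient 2's branch is an ideal diode here: no
resistance, no threshold dynamics — it only fixes the asymptote
``C2*PEEP2``.  One-way valve losses, tube resistance and tube compliance
are all neglected in this model; they live in the nonlinear simulator.

Units: cmH2O, L, s.  Compliances are litres per cmH2O (clinical mL/cmH2O
values are converted at the config-parsing layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateModelError

#: relative eigenvalue gap below which the system is flagged degenerate
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class LinearPatient:
    """One patient of the linear model.

    R [cmH2O/(L/s)], C [L/cmH2O], PEEP [cmH2O] and the exhalatory driving
    pressure DP = P(end inspiration) - PEEP [cmH2O].
    """

    R: float
    C: float
    PEEP: float = 5.0
    DP: float = 15.0

    def __post_init__(self):
        if self.R <= 0 or self.C <= 0:
            raise ConfigError("patient R and C must be positive")
        if self.PEEP < 0 or self.DP < 0:
            raise ConfigError("patient PEEP and DP must be non-negative")


@dataclass(frozen=True)
class LinearConfig:
    """Two patients plus the shared exhalation-valve resistance R_V."""

    p1: LinearPatient
    p2: LinearPatient
    R_V: float = 1.5

    def __post_init__(self):
        if self.R_V < 0:
            raise ConfigError("R_V must be non-negative")


@dataclass
class EigenSolution:
    """Eigen decomposition of the coupled discharge.

    ``lambda1 >= lambda2 > 0`` are the modal time constants [s]
    (``lambda1`` is the slow mode).  ``A1``, ``A2`` are the eigenvectors
    (unit Euclidean norm, first nonzero component positive), ``alpha`` and
    ``beta`` the mode amplitudes, and ``Vinf_i = C_i*PEEP_i`` the
    asymptotic volumes [L].
    """

    lambda1: float
    lambda2: float
    A1: np.ndarray
    A2: np.ndarray
    alpha: float = 0.0
    beta: float = 0.0
    Vinf1: float = 0.0
    Vinf2: float = 0.0
    degenerate: bool = field(default=False)


def system_matrices(cfg: LinearConfig):
    """Return ``(Cmat, Rmat, peep_vec)`` of the matrix-form discharge ODE."""
    p1, p2, rv = cfg.p1, cfg.p2, cfg.R_V
    cmat = np.diag([1.0 / p1.C, 1.0 / p2.C])
    rmat = np.array([[p1.R + rv, rv], [rv, p2.R + rv]])
    peep = np.array([p1.PEEP, p2.PEEP])
    return cmat, rmat, peep


def eigen_solution(cfg: LinearConfig, with_amplitudes: bool = True) -> EigenSolution:
    """Modal time constants and eigenvectors of the coupled discharge.

    The eigenvalues satisfy ``lam = (b +- sqrt(b^2 - 4c))/2`` with
    ``b = C1(R1+R_V) + C2(R2+R_V)`` and
    ``c = C1*C2*[(R1+R_V)(R2+R_V) - R_V^2]``; they are computed here from
    the 2x2 matrix ``diag(C).Rmat`` (same thing) and are always real and
    positive for physical parameters.
    """
    p1, p2 = cfg.p1, cfg.p2
    _, rmat, _ = system_matrices(cfg)
    m = np.diag([p1.C, p2.C]) @ rmat
    lam, vecs = np.linalg.eig(m)
    lam = np.real_if_close(lam)
    if np.iscomplexobj(lam):  # pragma: no cover - cannot happen physically
        raise DegenerateModelError("complex modal time constants")
    order = np.argsort(lam)[::-1]  # slow mode first
    lam = lam[order]
    vecs = np.real(vecs[:, order])
    # normalisation convention: unit norm, first nonzero component positive
    out = []
    for k in range(2):
        v = vecs[:, k] / np.linalg.norm(vecs[:, k])
        nz = np.nonzero(np.abs(v) > 1e-14)[0][0]
        if v[nz] < 0:
            v = -v
        out.append(v)
    degenerate = abs(lam[0] - lam[1]) <= _DEGENERATE_RTOL * abs(lam[0])
    if degenerate:
        # repeated eigenvalue: the matrix is diagonal(isable) with equal
        # modes; pick orthogonal axes so downstream solves stay regular
        out = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
    sol = EigenSolution(
        lambda1=float(lam[0]),
        lambda2=float(lam[1]),
        A1=out[0],
        A2=out[1],
        Vinf1=p1.C * p1.PEEP,
        Vinf2=p2.C * p2.PEEP,
        degenerate=degenerate,
    )
    if with_amplitudes:
        sol.alpha, sol.beta = mode_amplitudes(cfg, sol)
    return sol


def mode_amplitudes(cfg: LinearConfig, sol: EigenSolution) -> tuple[float, float]:
    """Solve ``(DP1*C1, DP2*C2) = alpha*A1 + beta*A2`` for the amplitudes.

    The right-hand side is the end-inspiratory volume excess over the
    asymptote, assuming null flow at the end of inspiration.
    """
    amat = np.column_stack([sol.A1, sol.A2])
    rhs = np.array([cfg.p1.DP * cfg.p1.C, cfg.p2.DP * cfg.p2.C])
    try:
        ab = np.linalg.solve(amat, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError("singular eigenvector matrix") from exc
    return float(ab[0]), float(ab[1])


def volume_trajectory(cfg: LinearConfig, sol: EigenSolution, t):
    """Lung volumes ``(V1, V2)`` [L] at time(s) ``t`` after expiration onset.

    ``V_i(t) = alpha*A1_i*e^(-t/lam1) + beta*A2_i*e^(-t/lam2) +
    C_i*PEEP_i``; at ``t=0`` this equals ``C_i*(DP_i + PEEP_i)`` and it
    relaxes to ``C_i*PEEP_i``.
    """
    t = np.asarray(t, dtype=float)
    e1 = np.exp(-t / sol.lambda1)
    e2 = np.exp(-t / sol.lambda2)
    v1 = sol.alpha * sol.A1[0] * e1 + sol.beta * sol.A2[0] * e2 + sol.Vinf1
    v2 = sol.alpha * sol.A1[1] * e1 + sol.beta * sol.A2[1] * e2 + sol.Vinf2
    return v1, v2


def nondimensional_groups(cfg: LinearConfig) -> tuple[float, float, float, float, float]:
    """The five ratios governing the nondimensional exhalation dynamics:
    ``(R2/R1, C2/C1, R_V/R1, DP2/DP1, PEEP2/PEEP1)``."""
    p1, p2 = cfg.p1, cfg.p2
    if p1.DP == 0 or p1.PEEP == 0:
        raise ConfigError("patient-1 DP and PEEP must be nonzero to form ratios")
    return (
        p2.R / p1.R,
        p2.C / p1.C,
        cfg.R_V / p1.R,
        p2.DP / p1.DP,
        p2.PEEP / p1.PEEP,
    )


def tau_reference(R: float, C: float, R_V: float, mode: str) -> float:
    """Closed-form reference time constants [s].

    ``shared_identical``: two identical patients sharing the valve,
    ``(R + 2*R_V)*C``; ``individual``: one patient alone on the ventilator,
    ``(R + R_V)*C``; ``lower_bound``: the uncoupled limit ``R*C`` (a lower
    bound for any asymmetric pairing).
    """
    if R <= 0 or C <= 0 or R_V < 0:
        raise ConfigError("need R, C > 0 and R_V >= 0")
    if mode == "shared_identical":
        return (R + 2.0 * R_V) * C
    if mode == "individual":
        return (R + R_V) * C
    if mode == "lower_bound":
        return R * C
    raise ConfigError(f"unknown tau_reference mode {mode!r}")


def nondimensional_trajectory(cfg: LinearConfig, t_hat):
    """Volumes scaled by ``C1*DP1`` on the time grid ``t_hat = t/(R1*C1)``.

    Two configurations sharing the five ratios produce identical curves —
    the scale-invariance behind the nondimensional sweep.
    """
    sol = eigen_solution(cfg)
    t = np.asarray(t_hat, dtype=float) * cfg.p1.R * cfg.p1.C
    v1, v2 = volume_trajectory(cfg, sol, t)
    scale = cfg.p1.C * cfg.p1.DP
    return (v1 - sol.Vinf1) / scale, (v2 - sol.Vinf2) / scale
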
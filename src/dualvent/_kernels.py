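"""Compiled right-hand side of the nonlinear network ODE.

The network state is six volumes: four capacitive-node stored volumes
(inspiratory split, expiratory merge, each patient airway opening) and the
two lung volumes.  Node pressures follow from the stored volumes, branch
flows from inverting each branch's monotone series pressure-drop law, and
the derivatives are the signed flow balances.  These routines mirror the
reference laws in :mod:`dualvent.components`; keep them in sync (a test
cross-checks them on a flow grid).

Everything is packed into flat float64 arrays so numba can compile one
generic kernel for any configuration.

Parameter vector layout (see the index constants below):
  [0:9]   ventilator waveform (period, t_ins, PEEP, P_max, zeta, omega,
          fall_mid, fall_k, critically-damped flag)
  [9]     patient-2-detached flag
  [16:86] seven branches x 10 slots:
          c_q2, c_lam, Re_coef, rel_rough, K, R_lin, P_crack, width,
          oneway flag, enabled flag
  [86:90] node compliances [L/cmH2O]

Branch order: 0 insp source->split, 1 merge->exp source, 2 split->merge
(short circuit, bidirectional), 3 split->airway1, 4 split->airway2,
5 airway1->merge, 6 airway2->merge.
"""

import math

import numpy as np
from numba import njit

IV_PERIOD, IV_TINS, IV_PEEP, IV_PMAX, IV_ZETA, IV_OMEGA, IV_FMID, IV_FK, IV_CRIT = range(9)
IV_DETACH2 = 9

NBRANCH = 7
BP0 = 16
BPS = 10
# per-branch slots
B_CQ2, B_CLAM, B_RECOEF, B_RR, B_K, B_RLIN, B_CRACK, B_WIDTH, B_ONEWAY, B_ENABLED = range(10)
NC0 = BP0 + NBRANCH * BPS  # node compliances start

NPARAM = NC0 + 4

# observe() output layout
NOBS = 14  # Psrc, Pni, Pne, Pa1, Pa2, q0..q6, qlung1, qlung2


@njit(cache=True)
def source_pressure(t, p):
    T = p[IV_PERIOD]
    tm = t % T
    if tm < 0.0:
        tm += T
    if tm >= T - 1e-12 * T:
        tm = 0.0
    peep = p[IV_PEEP]
    pmax = p[IV_PMAX]
    if tm < p[IV_TINS]:
        z = p[IV_ZETA]
        w = p[IV_OMEGA]
        if p[IV_CRIT] > 0.5:
            x = w * tm
            u = 1.0 - (1.0 + x) * math.exp(-x)
        else:
            wd = w * math.sqrt(1.0 - z * z)
            e = math.exp(-z * w * tm)
            u = 1.0 - e * (math.cos(wd * tm) + (z * w / wd) * math.sin(wd * tm))
        return peep + (pmax - peep) * u
    te = tm - p[IV_TINS]
    arg = (te - p[IV_FMID]) / p[IV_FK]
    if arg > 500.0:
        return peep
    return peep + (pmax - peep) / (1.0 + math.exp(arg))


@njit(cache=True)
def _haaland(Re, rr):
    inv = -1.8 * math.log10((rr / 3.7) ** 1.11 + 6.9 / Re)
    return 1.0 / (inv * inv)


@njit(cache=True)
def _tube_dp(q, c_q2, c_lam, recoef, rr):
    if c_q2 == 0.0:
        return 0.0
    a = abs(q)
    re = recoef * a
    if re < 2000.0:
        return c_lam * q
    if re >= 4000.0:
        f = _haaland(re, rr)
    else:
        f2 = 64.0 / 2000.0
        f4 = _haaland(4000.0, rr)
        f = f2 + (f4 - f2) * (re - 2000.0) / 2000.0
    return f * c_q2 * a * q


@njit(cache=True)
def _series_dp(q, bp):
    """Total pressure drop of one branch's series chain at flow q >= 0."""
    return _tube_dp(q, bp[B_CQ2], bp[B_CLAM], bp[B_RECOEF], bp[B_RR]) + bp[B_K] * q * abs(q) + bp[B_RLIN] * q


@njit(cache=True)
def _solve_pos(dp, q0, bp):
    """Invert the series law: the unique q >= 0 with series_dp(q) = dp > 0.

    Bracketed secant with bisection safeguard; q0 is a warm start from the
    previous evaluation.
    """
    tol = 1e-11 + 1e-9 * dp
    # initial guess: quadratic + linear terms only
    keff = bp[B_K] + bp[B_CQ2] * 0.03  # crude turbulent f ~ 0.03
    rlin = bp[B_RLIN] + bp[B_CLAM]
    if q0 > 1e-12:
        hi = q0
    elif keff > 0.0:
        hi = 2.0 * dp / (rlin + math.sqrt(rlin * rlin + 4.0 * keff * dp))
    elif rlin > 0.0:
        hi = dp / rlin
    else:
        return 0.0  # no resistance at all: treated as ideal connection upstream
    lo = 0.0
    flo = -dp
    fhi = _series_dp(hi, bp) - dp
    it = 0
    while fhi < 0.0 and it < 200:
        lo = hi
        flo = fhi
        hi *= 2.0
        fhi = _series_dp(hi, bp) - dp
        it += 1
    a = lo
    fa = flo
    b = hi
    fb = fhi
    q = b
    for _ in range(120):
        if fb != fa:
            q = b - fb * (b - a) / (fb - fa)
        else:
            q = 0.5 * (a + b)
        if q <= a or q >= b:
            q = 0.5 * (a + b)
        fq = _series_dp(q, bp) - dp
        if abs(fq) <= tol:
            return q
        if fq < 0.0:
            a = q
            fa = fq
        else:
            b = q
            fb = fq
        if b - a < 1e-15 * (1.0 + b):
            return 0.5 * (a + b)
    return q


@njit(cache=True)
def _branch_flow(pu, pd, bp, q0):
    """Signed flow through one branch given its end pressures."""
    if bp[B_ENABLED] == 0.0:
        return 0.0
    dp = pu - pd
    if bp[B_ONEWAY] > 0.5:
        x = dp - bp[B_CRACK]
        if x <= 0.0:
            return 0.0
        w = bp[B_WIDTH]
        dpe = x - 0.5 * w if x >= w else 0.5 * x * x / w
        if dpe <= 0.0:
            return 0.0
        return _solve_pos(dpe, q0, bp)
    if dp == 0.0:
        return 0.0
    if dp > 0.0:
        return _solve_pos(dp, abs(q0), bp)
    return -_solve_pos(-dp, abs(q0), bp)


@njit(cache=True)
def _interp(x, xs, ys):
    n = xs.shape[0]
    if n == 1:
        return ys[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    i = 1
    while xs[i] < x:
        i += 1
    f = (x - xs[i - 1]) / (xs[i] - xs[i - 1])
    return ys[i - 1] + f * (ys[i] - ys[i - 1])


@njit(cache=True)
def _lung_flow(paw, V, vg, cv, qg, rv):
    """Flow into the lung from its airway node [L/s]."""
    c = _interp(V, vg, cv)
    pel = V / c
    dpl = paw - pel
    if rv.shape[0] == 1:
        return dpl / rv[0]
    ql = dpl / rv[0]
    for _ in range(30):
        r = _interp(abs(ql), qg, rv)
        qn = dpl / r
        if abs(qn - ql) < 1e-12 + 1e-9 * abs(qn):
            return qn
        ql = 0.5 * (ql + qn)
    return ql


@njit(cache=True)
def _flows(t, y, p, lv1, lc1, lq1, lr1, lv2, lc2, lq2, lr2, qw, out):
    psrc = source_pressure(t, p)
    pni = y[0] / p[NC0]
    pne = y[1] / p[NC0 + 1]
    pa1 = y[2] / p[NC0 + 2]
    pa2 = y[3] / p[NC0 + 3]
    q0 = _branch_flow(psrc, pni, p[BP0 + 0 * BPS:BP0 + 1 * BPS], qw[0])
    q1 = _branch_flow(pne, psrc, p[BP0 + 1 * BPS:BP0 + 2 * BPS], qw[1])
    q2 = _branch_flow(pni, pne, p[BP0 + 2 * BPS:BP0 + 3 * BPS], qw[2])
    q3 = _branch_flow(pni, pa1, p[BP0 + 3 * BPS:BP0 + 4 * BPS], qw[3])
    q4 = _branch_flow(pni, pa2, p[BP0 + 4 * BPS:BP0 + 5 * BPS], qw[4])
    q5 = _branch_flow(pa1, pne, p[BP0 + 5 * BPS:BP0 + 6 * BPS], qw[5])
    q6 = _branch_flow(pa2, pne, p[BP0 + 6 * BPS:BP0 + 7 * BPS], qw[6])
    qw[0] = q0
    qw[1] = q1
    qw[2] = q2
    qw[3] = q3
    qw[4] = q4
    qw[5] = q5
    qw[6] = q6
    ql1 = _lung_flow(pa1, y[4], lv1, lc1, lq1, lr1)
    if p[IV_DETACH2] > 0.5:
        ql2 = 0.0
    else:
        ql2 = _lung_flow(pa2, y[5], lv2, lc2, lq2, lr2)
    out[0] = psrc
    out[1] = pni
    out[2] = pne
    out[3] = pa1
    out[4] = pa2
    out[5] = q0
    out[6] = q1
    out[7] = q2
    out[8] = q3
    out[9] = q4
    out[10] = q5
    out[11] = q6
    out[12] = ql1
    out[13] = ql2


@njit(cache=True)
def rhs(t, y, p, lv1, lc1, lq1, lr1, lv2, lc2, lq2, lr2, qw, obs):
    _flows(t, y, p, lv1, lc1, lq1, lr1, lv2, lc2, lq2, lr2, qw, obs)
    q0 = obs[5]
    q1 = obs[6]
    q2 = obs[7]
    q3 = obs[8]
    q4 = obs[9]
    q5 = obs[10]
    q6 = obs[11]
    ql1 = obs[12]
    ql2 = obs[13]
    dy = np.empty(6)
    dy[0] = q0 - q2 - q3 - q4
    dy[1] = q2 + q5 + q6 - q1
    dy[2] = q3 - q5 - ql1
    dy[3] = q4 - q6 - ql2
    dy[4] = ql1
    dy[5] = ql2
    return dy


@njit(cache=True)
def observe(t, y, p, lv1, lc1, lq1, lr1, lv2, lc2, lq2, lr2, qw):
    out = np.empty(NOBS)
    _flows(t, y, p, lv1, lc1, lq1, lr1, lv2, lc2, lq2, lr2, qw, out)
    return out
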
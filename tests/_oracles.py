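"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the coupled-discharge
oracle integrates the raw ODEs with a generic stiff solver instead of the
eigen decomposition, and the Colebrook oracle iterates the implicit
friction correlation instead of the explicit Haaland form.
"""

import math

import numpy as np
from scipy.integrate import solve_ivp


def integrate_linear_discharge(cfg, t_eval):
    """Brute-force integration of the coupled two-compartment discharge.

    dV/dt = Rmat^-1 (peep - Cmat V), starting from the end-inspiratory
    volumes C_i (DP_i + PEEP_i); tight tolerances so this serves as a
    reference for the closed-form solution.
    """
    p1, p2, rv = cfg.p1, cfg.p2, cfg.R_V
    cmat = np.diag([1.0 / p1.C, 1.0 / p2.C])
    rmat = np.array([[p1.R + rv, rv], [rv, p2.R + rv]])
    peep = np.array([p1.PEEP, p2.PEEP])
    rinv = np.linalg.inv(rmat)

    def f(_t, v):
        return rinv @ (peep - cmat @ v)

    v0 = np.array([p1.C * (p1.DP + p1.PEEP), p2.C * (p2.DP + p2.PEEP)])
    sol = solve_ivp(
        f,
        (float(t_eval[0]), float(t_eval[-1])),
        v0,
        method="Radau",
        rtol=1e-11,
        atol=1e-14,
        t_eval=t_eval,
    )
    assert sol.success
    return sol.y


def colebrook_friction(Re, rel_rough, n_iter=200):
    """Fixed-point iteration of the implicit Colebrook-White equation
    1/sqrt(f) = -2 log10(rr/3.7 + 2.51/(Re sqrt(f)))."""
    x = 1.0 / math.sqrt(0.02)  # x = 1/sqrt(f)
    for _ in range(n_iter):
        x = -2.0 * math.log10(rel_rough / 3.7 + 2.51 * x / Re)
    return 1.0 / x**2
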
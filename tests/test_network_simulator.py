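import numpy as np
import pytest

from dualvent import (
    CircuitConfig,
    LinearConfig,
    LinearPatient,
    LocalLoss,
    LungModel,
    VentilatorSettings,
    assemble_network,
    derivatives,
    eigen_solution,
    run_to_periodic,
    simulate,
    volume_trajectory,
)
from dualvent.components import PEEPValve, local_dp, tube_dp
from dualvent.errors import ConfigError
from dualvent.metrics import extract_expiration
from dualvent import _kernels as K

from conftest import linear_limit_cfg


class TestAssembly:
    def test_construction_counts(self, baseline_cfg):
        net = assemble_network(baseline_cfg)
        d = net.describe()
        assert d["n_lungs"] == 2
        assert len(d["capacitive_nodes"]) == 4
        assert len(d["branches"]) == 7
        assert len(d["enabled_branches"]) == 7

    def test_short_circuit_removable(self, baseline_cfg):
        net = assemble_network(baseline_cfg.with_(short_circuit=False))
        assert "short_circuit" not in net.describe()["enabled_branches"]

    def test_missing_tube_rejected(self, baseline_cfg):
        tubes = dict(baseline_cfg.tubes)
        tubes.pop("short_circuit")
        with pytest.raises(ConfigError):
            CircuitConfig(tubes=tubes)

    def test_branch_series_laws_monotone(self, baseline_cfg):
        """Every branch's series dP(q) is strictly increasing over the
        operating flow range."""
        net = assemble_network(baseline_cfg)
        qs = np.linspace(-5.0, 5.0, 201)
        for b in range(K.NBRANCH):
            bp = net.p[K.BP0 + b * K.BPS:K.BP0 + (b + 1) * K.BPS]
            dps = [K._series_dp(q, bp) for q in qs]
            assert np.all(np.diff(dps) > 0.0), net.branch_names[b]

    def test_kernel_matches_reference_laws(self, baseline_cfg):
        """The compiled branch law equals tube friction + localized losses
        computed with the pure-Python components."""
        net = assemble_network(baseline_cfg)
        # patient-1 expiratory branch: tube + (one-way + filter) quadratic
        b = net.branch_names.index("patient1_exp")
        bp = net.p[K.BP0 + b * K.BPS:K.BP0 + (b + 1) * K.BPS]
        tube = baseline_cfg.tubes["patient1_exp"]
        kq = LocalLoss(baseline_cfg.oneway.K + baseline_cfg.filter.K)
        for q in np.linspace(-3.0, 3.0, 31):
            expect = tube_dp(tube, q) + local_dp(kq, q)
            assert K._series_dp(q, bp) == pytest.approx(expect, rel=1e-12, abs=1e-14)


class TestDerivatives:
    def test_equilibrium_is_stationary(self, baseline_cfg):
        net = assemble_network(baseline_cfg)
        y = net.initial_state()
        # late expiration: source at PEEP, everything at PEEP -> no flow
        t = baseline_cfg.ventilator.t_ins + 0.9 * baseline_cfg.ventilator.t_ex
        dy = derivatives(y, t, net)
        assert np.max(np.abs(dy)) < 1e-9

    def test_expiration_sign(self, baseline_cfg):
        net = assemble_network(baseline_cfg)
        y = net.initial_state()
        y[4] = y[5] = 0.035 * 20.0  # lungs pressurised to 20 cmH2O
        t = baseline_cfg.ventilator.t_ins + 1.0  # source back at PEEP
        dy = derivatives(y, t, net)
        assert dy[4] < 0.0 and dy[5] < 0.0

    def test_node_balance_consistency(self, baseline_cfg):
        """dV/dt at every node equals the signed sum of incident branch
        flows reported by the observables."""
        net = assemble_network(baseline_cfg)
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = net.initial_state() * rng.uniform(0.5, 2.0, 6)
            t = rng.uniform(0.0, baseline_cfg.ventilator.period)
            dy = derivatives(y, t, net)
            o = net.observe(t, y)
            q = o[5:12]
            ql1, ql2 = o[12], o[13]
            balance = np.array(
                [
                    q[0] - q[2] - q[3] - q[4],
                    q[2] + q[5] + q[6] - q[1],
                    q[3] - q[5] - ql1,
                    q[4] - q[6] - ql2,
                    ql1,
                    ql2,
                ]
            )
            # rhs and observe invert the branch laws independently; they
            # agree to the branch solver's own tolerance (~1e-9 * dp)
            np.testing.assert_allclose(dy, balance, rtol=0, atol=5e-8)

    def test_total_volume_conservation_identity(self, baseline_cfg):
        """Total stored volume changes only through the ventilator ports."""
        net = assemble_network(baseline_cfg)
        rng = np.random.default_rng(11)
        for _ in range(10):
            y = net.initial_state() * rng.uniform(0.5, 2.0, 6)
            t = rng.uniform(0.0, baseline_cfg.ventilator.period)
            dy = derivatives(y, t, net)
            o = net.observe(t, y)
            assert np.sum(dy) == pytest.approx(o[5] - o[6], abs=5e-8)


class TestSimulate:
    def test_symmetric_tidal_volumes(self):
        cfg = CircuitConfig(peep_valve=PEEPValve(P_thresh=0.0, K_PEEP=LocalLoss(0.0)))
        res = run_to_periodic(cfg)
        row = res.cycles.iloc[-1]
        assert abs(row.VT1 - row.VT2) / row.VT1 < 0.01

    def test_cycle_mass_balance_at_steady_state(self, baseline_cfg):
        res = run_to_periodic(baseline_cfg)
        # inhaled = exhaled per cycle: start and end volumes agree within
        # 1% of the tidal volume
        for v, vt in ((res.V1, res.cycles.iloc[-1].VT1), (res.V2, res.cycles.iloc[-1].VT2)):
            assert abs(v[-1] - v[0]) / vt < 0.01

    def test_tolerance_refinement(self, baseline_cfg):
        r3 = simulate(baseline_cfg, n_cycles=3, rtol=1e-3)
        r6 = simulate(baseline_cfg, n_cycles=3, rtol=1e-6)
        for col in ("VT1", "VT2"):
            a = r3.cycles.iloc[-1][col]
            b = r6.cycles.iloc[-1][col]
            assert abs(a - b) / b < 0.01

    def test_sampling_density(self, baseline_cfg):
        res = simulate(baseline_cfg, n_cycles=1)
        assert len(res.t) >= 200

    def test_no_reverse_flow_through_check_valves(self, baseline_cfg):
        res = run_to_periodic(baseline_cfg)
        for name in ("insp_source", "exp_source", "patient1_insp",
                     "patient2_insp", "patient1_exp", "patient2_exp"):
            assert res.flow(name).min() >= -1e-12, name


class TestRunToPeriodic:
    def test_fast_settling_linear_case(self):
        from dualvent.components import ExhalationValve

        cfg = linear_limit_cfg(exhalation_valve=ExhalationValve(R_V=0.0))
        res = run_to_periodic(cfg)
        assert res.periodic
        assert res.cycles_to_converge <= 5

    def test_already_periodic_state_converges_immediately(self, baseline_cfg):
        first = run_to_periodic(baseline_cfg, tol_rel=1e-4)
        again = run_to_periodic(baseline_cfg, init_state=first.final_state)
        assert again.periodic
        # one cycle to re-measure, one to confirm
        assert again.cycles_to_converge <= 2

    def test_autopeep_regime_traps_volume(self):
        # long time constants vs a short expiratory window: the lungs
        # cannot empty and end-expiratory volume settles above C*PEEP
        vent = VentilatorSettings(BR=30.0, t_ins=1.0)  # t_ex = 1 s
        cfg = CircuitConfig(
            ventilator=vent,
            lung1=LungModel(C_law=0.05, R_law=10.0),
            lung2=LungModel(C_law=0.05, R_law=10.0),
        )
        res = run_to_periodic(cfg, max_cycles=80)
        eev_relaxed = 0.05 * 5.0
        assert res.cycles.iloc[-1].EEV1 > eev_relaxed * 1.1
        t, v = extract_expiration(res, 1)
        assert v[-1] > eev_relaxed * 1.1


class TestLinearLimitOracle:
    def test_expiration_matches_linear_model(self):
        """With constant lungs, zero losses and ideal tubes/valves, the
        simulated expiratory volumes follow the closed-form
        two-compartment solution to within 2%."""
        cfg = linear_limit_cfg(
            lung1=LungModel(C_law=0.035, R_law=5.0),
            lung2=LungModel(C_law=0.0425, R_law=8.0),
        )
        res = run_to_periodic(cfg)
        t1, v1s = extract_expiration(res, 1)
        t2, v2s = extract_expiration(res, 2)
        lin = LinearConfig(
            p1=LinearPatient(R=5.0, C=0.035, PEEP=5.0, DP=v1s[0] / 0.035 - 5.0),
            p2=LinearPatient(R=8.0, C=0.0425, PEEP=5.0, DP=v2s[0] / 0.0425 - 5.0),
            R_V=1.5,
        )
        sol = eigen_solution(lin)
        for pat, (t, vs) in ((1, (t1, v1s)), (2, (t2, v2s))):
            va, vb = volume_trajectory(lin, sol, t)
            ref = va if pat == 1 else vb
            scale = ref[0] - ref[-1]
            assert np.max(np.abs(vs - ref)) / scale < 0.02
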
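import numpy as np
import pytest

from dualvent.errors import ConfigError
from dualvent.linear import (
    LinearConfig,
    LinearPatient,
    eigen_solution,
    nondimensional_groups,
    nondimensional_trajectory,
    system_matrices,
    tau_reference,
    volume_trajectory,
)

from _oracles import integrate_linear_discharge

BASE1 = LinearPatient(R=5.0, C=0.035, PEEP=5.0, DP=15.0)


def symmetric(rv=1.5):
    return LinearConfig(p1=BASE1, p2=BASE1, R_V=rv)


def asymmetric(rv=1.5):
    return LinearConfig(
        p1=BASE1, p2=LinearPatient(R=8.0, C=0.0425, PEEP=5.0, DP=15.0), R_V=rv
    )


def random_config(rng):
    def pat():
        return LinearPatient(
            R=rng.uniform(2.0, 12.0),
            C=rng.uniform(0.02, 0.06),
            PEEP=rng.uniform(0.0, 12.0),
            DP=rng.uniform(5.0, 25.0),
        )

    return LinearConfig(p1=pat(), p2=pat(), R_V=rng.uniform(0.0, 4.0))


class TestSystemMatrices:
    def test_decoupled_when_rv_zero(self):
        _, rmat, _ = system_matrices(symmetric(rv=0.0))
        assert rmat[0, 1] == rmat[1, 0] == 0.0

    def test_baseline_resistance_matrix(self):
        # R1 = R2 = 5, calibrated R_V = 1.5 -> [[6.5, 1.5], [1.5, 6.5]]
        _, rmat, _ = system_matrices(symmetric())
        np.testing.assert_allclose(rmat, [[6.5, 1.5], [1.5, 6.5]])

    def test_symmetry_generic(self, rng):
        for _ in range(10):
            _, rmat, _ = system_matrices(random_config(rng))
            assert rmat[0, 1] == rmat[1, 0]


class TestEigenSolution:
    def test_decoupled_rc(self):
        sol = eigen_solution(symmetric(rv=0.0))
        assert sol.lambda1 == pytest.approx(0.175, rel=1e-12)
        assert sol.lambda2 == pytest.approx(0.175, rel=1e-12)
        assert sol.degenerate

    def test_symmetric_modes(self):
        # slow mode (R + 2 R_V) C, fast mode R C
        sol = eigen_solution(symmetric())
        assert sol.lambda1 == pytest.approx(0.28, rel=1e-12)
        assert sol.lambda2 == pytest.approx(0.175, rel=1e-12)

    def test_matches_generic_eigensolver(self, rng):
        for _ in range(20):
            cfg = random_config(rng)
            sol = eigen_solution(cfg)
            _, rmat, _ = system_matrices(cfg)
            m = np.diag([cfg.p1.C, cfg.p2.C]) @ rmat
            ref = np.sort(np.linalg.eigvals(m))[::-1]
            assert sol.lambda1 == pytest.approx(ref[0].real, rel=1e-10)
            assert sol.lambda2 == pytest.approx(ref[1].real, rel=1e-10)
            assert sol.lambda1 >= sol.lambda2 > 0


class TestModeAmplitudes:
    def test_symmetric_single_mode(self):
        sol = eigen_solution(symmetric())
        # equal patients and DP: antisymmetric-mode amplitude vanishes
        anti = min(abs(sol.alpha), abs(sol.beta))
        assert anti == pytest.approx(0.0, abs=1e-12)

    def test_zero_dp_constant_volumes(self):
        p = LinearPatient(R=5.0, C=0.035, PEEP=5.0, DP=0.0)
        cfg = LinearConfig(p1=p, p2=p, R_V=1.5)
        sol = eigen_solution(cfg)
        assert sol.alpha == pytest.approx(0.0, abs=1e-12)
        assert sol.beta == pytest.approx(0.0, abs=1e-12)
        v1, v2 = volume_trajectory(cfg, sol, np.array([0.0, 1.0]))
        np.testing.assert_allclose(v1, p.C * p.PEEP)

    def test_amplitudes_reconstruct_initial_excess(self):
        cfg = asymmetric()
        sol = eigen_solution(cfg)
        rhs = sol.alpha * sol.A1 + sol.beta * sol.A2
        np.testing.assert_allclose(
            rhs,
            [cfg.p1.DP * cfg.p1.C, cfg.p2.DP * cfg.p2.C],
            rtol=1e-12,
        )


class TestVolumeTrajectory:
    def test_initial_and_asymptotic_volumes(self):
        cfg = symmetric()
        sol = eigen_solution(cfg)
        v1, v2 = volume_trajectory(cfg, sol, np.array([0.0, 100.0]))
        assert v1[0] == pytest.approx(0.70, rel=1e-9)  # C (DP + PEEP)
        assert v1[-1] == pytest.approx(0.175, rel=1e-6)  # C PEEP
        np.testing.assert_allclose(v1, v2, rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_stiff_integration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            cfg = random_config(rng)
            sol = eigen_solution(cfg)
            t = np.linspace(0.0, 2.0, 80)
            v1, v2 = volume_trajectory(cfg, sol, t)
            ref = integrate_linear_discharge(cfg, t)
            scale = np.abs(ref).max()
            assert np.max(np.abs(np.vstack([v1, v2]) - ref)) / scale < 1e-6


class TestNondimensionalGroups:
    def test_identical_patients(self):
        g = nondimensional_groups(symmetric())
        assert g == pytest.approx((1.0, 1.0, 0.3, 1.0, 1.0))

    def test_compliance_ratio(self):
        g = nondimensional_groups(asymmetric())
        assert g[1] == pytest.approx(0.0425 / 0.035)
        assert g[1] == pytest.approx(1.2143, abs=5e-5)

    def test_zero_denominator_rejected(self):
        p = LinearPatient(R=5.0, C=0.035, PEEP=0.0, DP=15.0)
        with pytest.raises(ConfigError):
            nondimensional_groups(LinearConfig(p1=p, p2=BASE1, R_V=1.5))


class TestTauReference:
    def test_closed_forms(self):
        assert tau_reference(5.0, 0.035, 1.5, "shared_identical") == pytest.approx(0.28)
        assert tau_reference(5.0, 0.035, 1.5, "individual") == pytest.approx(0.2275)
        assert tau_reference(5.0, 0.035, 1.5, "lower_bound") == pytest.approx(0.175)

    def test_collapse_at_rv_zero(self):
        vals = {
            m: tau_reference(5.0, 0.035, 0.0, m)
            for m in ("shared_identical", "individual", "lower_bound")
        }
        assert len(set(vals.values())) == 1

    def test_ordering_strict_with_rv(self, rng):
        for _ in range(20):
            r, c, rv = rng.uniform(1, 12), rng.uniform(0.01, 0.08), rng.uniform(0.1, 4)
            shared = tau_reference(r, c, rv, "shared_identical")
            indiv = tau_reference(r, c, rv, "individual")
            lower = tau_reference(r, c, rv, "lower_bound")
            assert shared > indiv > lower


class TestScaleInvariance:
    def test_same_ratios_same_nondimensional_trajectories(self):
        t_hat = np.linspace(0.0, 8.0, 50)
        cfg_a = asymmetric()
        # double resistances/pressures, halve compliances: same five
        # ratios and same R1*C1, so the nondimensional curves must agree
        cfg_b = LinearConfig(
            p1=LinearPatient(R=10.0, C=0.0175, PEEP=10.0, DP=30.0),
            p2=LinearPatient(R=16.0, C=0.02125, PEEP=10.0, DP=30.0),
            R_V=3.0,
        )
        va = nondimensional_trajectory(cfg_a, t_hat)
        vb = nondimensional_trajectory(cfg_b, t_hat)
        np.testing.assert_allclose(va, vb, rtol=1e-9, atol=1e-12)
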
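import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualvent.components import (
    CheckValve,
    LocalLoss,
    LungModel,
    TubeSegment,
    check_valve_q,
    friction_factor,
    local_dp,
    lung_pressure,
    tube_dp,
    tube_stored_volume,
)
from dualvent.errors import ConfigError

from _oracles import colebrook_friction

TUBE = TubeSegment(L=1.0, D=0.020)


class TestFrictionFactor:
    def test_laminar(self):
        assert friction_factor(1000.0) == pytest.approx(0.064, rel=1e-12)

    def test_turbulent_vs_colebrook(self):
        for re, rr in [(1e5, 0.01), (2e4, 0.001), (5e4, 0.02)]:
            f = friction_factor(re, rr)
            assert f == pytest.approx(colebrook_friction(re, rr), rel=0.02)

    def test_blend_continuity(self):
        for re in (2000.0, 4000.0):
            below = friction_factor(re - 1e-9, 0.01)
            above = friction_factor(re + 1e-9, 0.01)
            assert abs(below - above) < 1e-10

    def test_negative_re_rejected(self):
        with pytest.raises(ConfigError):
            friction_factor(-1.0)


class TestTubeDp:
    def test_zero_flow(self):
        assert tube_dp(TUBE, 0.0) == 0.0

    @given(st.floats(min_value=0.001, max_value=5.0))
    @settings(derandomize=True, max_examples=50)
    def test_odd_symmetry(self, q):
        assert tube_dp(TUBE, -q) == pytest.approx(-tube_dp(TUBE, q), rel=1e-12)

    def test_laminar_limit_is_hagen_poiseuille(self):
        q = 0.2  # L/s -> Re ~ 850, laminar
        dp = tube_dp(TUBE, q)
        hp_pa = 128.0 * TUBE.mu * TUBE.L * (q * 1e-3) / (math.pi * TUBE.D**4)
        assert dp == pytest.approx(hp_pa / 98.0665, rel=0.01)

    def test_dissipative(self):
        for q in np.linspace(-4, 4, 41):
            assert tube_dp(TUBE, q) * q >= 0.0


class TestTubeStorage:
    def test_zero_pressure(self):
        assert tube_stored_volume(TUBE, 0.0) == 0.0

    def test_typical_compliance(self):
        # 1 mL/cmH2O per metre at 10 cmH2O -> 10 mL
        assert tube_stored_volume(TUBE, 10.0) == pytest.approx(0.010)

    def test_linearity_and_override(self):
        assert tube_stored_volume(TUBE, 20.0) == pytest.approx(
            2 * tube_stored_volume(TUBE, 10.0)
        )
        t = TubeSegment(L=1.0, D=0.020, dVdP=2e-3)
        assert tube_stored_volume(t, 10.0) == pytest.approx(0.020)


class TestLocalLoss:
    def test_peep_valve_drop(self):
        loss = LocalLoss.from_tagged(0.0012, "cmH2O/(L/min)^2")
        assert local_dp(loss, 0.5) == pytest.approx(1.08)  # 30 L/min

    def test_oneway_drop_at_60_lmin(self):
        loss = LocalLoss.from_tagged(9.01e-4, "cmH2O/(L/min)^2")
        assert local_dp(loss, 1.0) == pytest.approx(3.2436)

    def test_zero_flow(self):
        assert local_dp(LocalLoss(4.32), 0.0) == 0.0

    def test_unit_round_trip_exact(self):
        # vendor-units coefficient reproduces the printed drop at the
        # printed flow to machine precision after conversion
        for k_lmin, q_lmin in [(1.24e-3, 45.0), (4.8e-4, 60.0), (9.01e-4, 25.0)]:
            loss = LocalLoss.from_tagged(k_lmin, "cmH2O/(L/min)^2")
            got = local_dp(loss, q_lmin / 60.0)
            assert got == pytest.approx(k_lmin * q_lmin**2, rel=1e-12)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ConfigError):
            LocalLoss.from_tagged(1.0, "psi/(gpm)^2")


class TestCheckValve:
    VALVE = CheckValve(P_crack=2.0, smoothing_width=0.01)
    K = 4.32

    def series(self, q):
        return self.K * q * abs(q)

    def test_closed_at_zero_dp(self):
        assert check_valve_q(self.VALVE, 0.0, self.series) == 0.0
        assert check_valve_q(self.VALVE, 1.99, self.series) == 0.0

    def test_quadratic_inversion_far_above_crack(self):
        dp = 12.0
        q = check_valve_q(self.VALVE, dp, self.series)
        expect = math.sqrt((dp - self.VALVE.P_crack - 0.005) / self.K)
        assert q == pytest.approx(expect, rel=1e-6)

    def test_monotone_and_nonnegative(self):
        dps = np.linspace(0.0, 10.0, 200)
        qs = [check_valve_q(self.VALVE, dp, self.series) for dp in dps]
        assert min(qs) >= 0.0
        assert np.all(np.diff(qs) >= -1e-12)


class TestLung:
    def test_elastic_recoil(self):
        lung = LungModel(C_law=0.035, R_law=5.0)
        assert lung_pressure(lung, 0.525, 0.0) == pytest.approx(15.0)
        assert lung_pressure(lung, 0.0, 0.0) == 0.0

    def test_affine_in_flow_for_constant_laws(self):
        lung = LungModel(C_law=0.035, R_law=5.0)
        p0 = lung_pressure(lung, 0.3, 0.0)
        for q in (-1.0, -0.2, 0.4, 1.5):
            assert lung_pressure(lung, 0.3, q) == pytest.approx(p0 + 5.0 * q)

    def test_tabulated_laws(self):
        c_tab = (np.array([0.0, 0.4, 0.8]), np.array([0.04, 0.035, 0.03]))
        r_tab = (np.array([0.0, 1.0]), np.array([5.0, 8.0]))
        lung = LungModel(C_law=c_tab, R_law=r_tab)
        assert lung.compliance(0.2) == pytest.approx(0.0375)
        assert lung.resistance(0.5) == pytest.approx(6.5)
        with pytest.raises(ConfigError):
            lung_pressure(lung, 1.5, 0.0)  # outside tabulated range

    def test_volume_at_pressure_fixed_point(self):
        c_tab = (np.array([0.0, 0.4, 0.8]), np.array([0.04, 0.035, 0.03]))
        lung = LungModel(C_law=c_tab, R_law=5.0)
        v = lung.volume_at_pressure(8.0)
        assert v / lung.compliance(v) == pytest.approx(8.0, rel=1e-8)

    def test_invalid_laws_rejected(self):
        with pytest.raises(ConfigError):
            LungModel(C_law=-0.01)
        with pytest.raises(ConfigError):
            LungModel(C_law=(np.array([0.0, 1.0]), np.array([0.035, -0.1])))
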
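import numpy as np
import pytest

from dualvent import CircuitConfig, LocalLoss, LungModel, VentilatorSettings
from dualvent.components import PEEPValve
from dualvent.sweep import SweepSpec, run_sweep


@pytest.fixture(scope="session")
def baseline_cfg() -> CircuitConfig:
    """Standard operating point: Table-style ventilator settings, default
    circuit losses, identical 35 mL/cmH2O / 5 cmH2O/(L/s) patients."""
    return CircuitConfig()


def linear_limit_cfg(**overrides) -> CircuitConfig:
    """Configuration realising the analytic linear model's premises:
    constant lung laws, no localized losses, ideal (rigid, frictionless)
    tubes, no short circuit, and a near-instant source fall (the linear
    model assumes the source steps to PEEP at expiration onset)."""
    kw = dict(
        ventilator=VentilatorSettings(fall_midpoint=0.002, fall_steepness=0.001),
        oneway=LocalLoss(0.0),
        filter=LocalLoss(0.0),
        peep_valve=PEEPValve(P_thresh=0.0, K_PEEP=LocalLoss(0.0)),
        ideal_tubes=True,
        short_circuit=False,
    )
    kw.update(overrides)
    return CircuitConfig(**kw)


@pytest.fixture(scope="session")
def symmetric_linear_limit() -> CircuitConfig:
    return linear_limit_cfg()


@pytest.fixture(scope="session")
def asymmetric_linear_limit() -> CircuitConfig:
    return linear_limit_cfg(
        lung1=LungModel(C_law=0.035, R_law=5.0),
        lung2=LungModel(C_law=0.0425, R_law=8.0),
    )


@pytest.fixture(scope="session")
def study_sweep() -> "pandas.DataFrame":  # noqa: F821
    """The reduced parametric-study grid (3x3 patient-2 mechanics x 9
    ventilation-ratio combinations) run once and shared by the tests that
    examine it."""
    return run_sweep(SweepSpec())


@pytest.fixture(scope="session")
def study_spec() -> SweepSpec:
    return SweepSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
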
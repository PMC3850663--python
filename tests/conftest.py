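"""Shared fixtures: the three study scenarios are integrated once per session."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import cervixsim as cx

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params() -> cx.ModelParameters:
    return cx.ModelParameters()


def _run_default(mode: str) -> cx.SimulationResult:
    return cx.integrate(
        cx.ModelParameters(),
        cx.ControllerConfig(mode=cx.ControlMode.parse(mode)),
    )


@pytest.fixture(scope="session")
def pin_result() -> cx.SimulationResult:
    return _run_default("pin")


@pytest.fixture(scope="session")
def sliding_result() -> cx.SimulationResult:
    return _run_default("sliding")


@pytest.fixture(scope="session")
def both_result() -> cx.SimulationResult:
    return _run_default("both")


@pytest.fixture()
def fast_controller() -> cx.ControllerConfig:
    """A sped-up protocol (10 cm/hr, 5 min ramp) for solver-machinery tests."""
    return cx.ControllerConfig(
        desired_diameter_rate=10.0 / 3.6e5, ramp_duration=300.0
    )
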
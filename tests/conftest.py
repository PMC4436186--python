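import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from legacylag import ExponentialTTD, OutletModel, ScenarioSpec, SourceZoneParams, walnut_creek

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def walnut_cfg():
    return walnut_creek()


@pytest.fixture(scope="session")
def walnut_source(walnut_cfg) -> SourceZoneParams:
    """Walnut Creek source-zone parameter set (lambda = 0.16/y)."""
    return walnut_cfg.source


@pytest.fixture(scope="session")
def scenario_source(walnut_source) -> SourceZoneParams:
    """Faster-depletion source variant (lambda = 0.23/y) used for scenario comparisons."""
    from dataclasses import replace

    return replace(walnut_source, lam=0.23)


@pytest.fixture(scope="session")
def exp_ttd() -> ExponentialTTD:
    return ExponentialTTD(mu=21.6)


def make_model(source, pattern="random", p=0.5, mu=21.6, k=0.18) -> OutletModel:
    return OutletModel(source, ExponentialTTD(mu=mu), k, ScenarioSpec(pattern, p))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240501)
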
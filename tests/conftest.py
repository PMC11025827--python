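import warnings

import pytest
from hypothesis import HealthCheck, settings

from lvelastance import ModelParams
from lvelastance.elastance import run_elastance_study
from lvelastance.simulator import run_to_limit_cycle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def trace(params):
    """Converged default run (R_out = 1050) at full resolution."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_to_limit_cycle(params)


@pytest.fixture(scope="session")
def study(params):
    """The full five-afterload elastance experiment at study conditions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_elastance_study(params, keep_traces=True)
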
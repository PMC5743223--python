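import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
    max_examples=25,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A scaled-down generator configuration for fast tests."""
    from clonepotency.synthetic_data import SimulationParams

    params = SimulationParams(seed=11)
    params.n_clones = {s: max(10, n // 10) for s, n in params.n_clones.items()}
    return params


@pytest.fixture
def small_table(small_params):
    from clonepotency.synthetic_data import simulate_clone_table

    return simulate_clone_table(small_params)


@pytest.fixture
def productive_profiles(small_table):
    from clonepotency.potency_metrics import PositivityThresholds, bias_profile, call_positivity

    thr = PositivityThresholds()
    return [
        bias_profile(rec, thr) for rec in small_table if call_positivity(rec, thr)[1]
    ]
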
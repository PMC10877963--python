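import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trial_df():
    """A 2-participant simulated trial (one per staff group), session-wide."""
    from tracheoguide import simulate as sim

    dataset = sim.simulate_trial(
        design=sim.TrialDesign(n_participants_per_group=1), master_seed=42
    )
    return dataset.to_dataframe()
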
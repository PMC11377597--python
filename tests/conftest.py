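import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240722)


@pytest.fixture
def small_cfg():
    """A compact simulation config for unit tests (12^3 grid, small cohorts)."""
    from tauvbm.simulate import Hotspot, SimulationConfig

    return SimulationConfig(
        seed=11,
        grid_dims=(12, 12, 12),
        n_controls=20,
        n_athletes=12,
        tau_hotspots=(
            Hotspot((3, 8, 7), 2.5, 0.5),
            Hotspot((8, 8, 7), 2.5, 0.5),
        ),
    )
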
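import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    from adhesim import ModelParams

    return ModelParams()


@pytest.fixture
def small_params():
    """Cheap parameter set for protocol-level tests (few sites, short runs)."""
    from adhesim import ModelParams

    return ModelParams(n_cc=10, n_cm=10, t_total=0.2)


def random_cell(rng, center, n_cc=8, n_cm=8, radius=1.0):
    from adhesim import CellState
    from adhesim.geometry import sample_uniform_sphere

    return CellState(
        center=np.asarray(center, float),
        radius=radius,
        cc_dirs=sample_uniform_sphere(n_cc, rng),
        cm_dirs=sample_uniform_sphere(n_cm, rng),
    )
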
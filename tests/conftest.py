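import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_truth():
    from operonatlas.simulate import TruthSpec, generate_truth

    return generate_truth(TruthSpec(seed=11, n_operons=8, genome_length=80_000))
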
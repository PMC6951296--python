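import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_rule_partition():
    from tskallometry import FuzzyPartition

    return FuzzyPartition(theta=np.array([0.0, 2.0]), lam=np.array([1.0, 2.0]))


@pytest.fixture
def biphasic_data():
    """A moderate biphasic dataset with known ground truth."""
    from tskallometry import GeneratorSpec, generate

    spec = GeneratorSpec(n=2000, seed=7)
    return generate(spec)


@pytest.fixture
def small_csv(tmp_path):
    p = tmp_path / "data.csv"
    p.write_text("x,y\n1.0,2.0\n2.0,4.0\n3.0,6.0\n")
    return p
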
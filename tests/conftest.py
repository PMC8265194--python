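import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exonskip.features import CONCENTRATION_FEATURE
from exonskip.model import ModelSpec, TrainingData, fit_model
from exonskip.synthetic import SyntheticConfig, generate_dataset, protocol_registry, random_context

settings.register_profile(
    "repro", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def toy_context():
    """Deterministic 100-base exon with 200-base intron flanks."""
    return random_context(100, gc_fraction=0.5, seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset with planted (concentration, GC, ACP) signal."""
    return generate_dataset(SyntheticConfig(n_records=120, seed=5), protocol_registry())


@pytest.fixture(scope="session")
def small_training_data(small_dataset):
    return TrainingData(small_dataset.X, small_dataset.y, small_dataset.groups)


@pytest.fixture(scope="session")
def toy_model(small_training_data):
    """A fixed-subset model, fitted without any search (fast)."""
    spec = ModelSpec(
        feature_names=(CONCENTRATION_FEATURE, "GCs (number of)", "ACP"),
        C=10.0, gamma=0.1, epsilon=0.1, chemistry="PMO",
    )
    return fit_model(small_training_data, spec, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
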
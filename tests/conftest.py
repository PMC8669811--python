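import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aipkit import FeatureMatrix, PeptideRecord, PeptideSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")


@pytest.fixture
def tiny_set() -> PeptideSet:
    """Four short labelled peptides covering both classes."""
    return PeptideSet(
        [
            PeptideRecord("P1", "AAAAC", 1),
            PeptideRecord("P2", "ACDEF", 1),
            PeptideRecord("P3", "GGGGG", 0),
            PeptideRecord("P4", "KLMNP", 0),
        ]
    )


@pytest.fixture
def separable_matrix() -> FeatureMatrix:
    """40 samples; feature 0 separates the classes perfectly, the other
    four are label-independent noise."""
    rng = np.random.default_rng(7)
    y = np.array([1] * 20 + [0] * 20)
    X = rng.normal(size=(40, 5))
    X[:, 0] = np.where(y == 1, 1.0, -1.0) + rng.normal(scale=0.05, size=40)
    return FeatureMatrix(
        X,
        [f"f{i}" for i in range(5)],
        [f"s{i}" for i in range(40)],
        y,
    )
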
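import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from optsep.data_io import CountTable, LabelVector

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_table() -> CountTable:
    counts = np.array(
        [
            [5.0, 40.0, 2.0, 0.0],
            [0.0, 30.0, 5.0, 0.0],
            [0.0, 30.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return CountTable(
        ["s1", "s2", "s3", "s4"], ["spA", "spB", "spC", "spD"], counts
    )


@pytest.fixture
def tiny_labels(tiny_table) -> LabelVector:
    return LabelVector(tiny_table.sample_ids, [0, 0, 1, 1])


@pytest.fixture
def blobs():
    """Two well-separated 2-d point clouds, 20 samples per class."""
    rng = np.random.default_rng(7)
    X0 = rng.normal(loc=(-3.0, 0.0), scale=0.3, size=(20, 2))
    X1 = rng.normal(loc=(3.0, 0.0), scale=0.3, size=(20, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 20 + [1] * 20)
    return X, y
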
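import numpy as np
import pytest

from ecgtopo.ecg_io import ECGRecord
from ecgtopo.embedding import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def twelve_lead_record(rng):
    samples = rng.standard_normal((12, 5000))
    names = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]
    return ECGRecord(samples=samples, fs=500.0, lead_names=names, label="acceptable", record_id="r12")


@pytest.fixture
def unit_square_cloud():
    return PointCloud(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))


def random_cloud(rng, max_points=8, dim=3):
    n = int(rng.integers(2, max_points + 1))
    return PointCloud(rng.uniform(-1, 1, size=(n, dim)))
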
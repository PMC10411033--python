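import numpy as np
import pytest

from rfsafe import FieldMap, Modality


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sar_map(rng):
    values = rng.uniform(0.5, 5.0, size=(16, 16))
    return FieldMap(values=values, spacing=(2.0, 2.0), modality=Modality.SAR, norm_power=8.0)


@pytest.fixture
def disk_mask():
    y, x = np.mgrid[:32, :32]
    return (x - 15.5) ** 2 + (y - 15.5) ** 2 <= 13.0**2


def make_map(values, modality=Modality.SAR, spacing=(1.0, 1.0), **kw):
    return FieldMap(values=np.asarray(values, dtype=float), spacing=spacing, modality=modality, **kw)
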
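import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tracershift import Box3D, Detection, Spacing, default_binning

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def spacing445() -> Spacing:
    """The working resampling grid: 4 x 4 x 5 mm voxels (0.08 cc each)."""
    return Spacing(4.0, 4.0, 5.0)


@pytest.fixture
def unit_spacing() -> Spacing:
    return Spacing(1.0, 1.0, 1.0)


@pytest.fixture
def bins10():
    return default_binning()


def random_box(rng: np.random.Generator, lo: float = 0.0, hi: float = 40.0) -> Box3D:
    c = rng.uniform(lo + 5, hi - 5, size=3)
    e = rng.uniform(1.0, 10.0, size=3)
    return Box3D.from_center_extent(c, e)


def random_detections(rng: np.random.Generator, n: int) -> list[Detection]:
    return [Detection(random_box(rng), float(rng.uniform(0, 1))) for _ in range(n)]
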
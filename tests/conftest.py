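import numpy as np
import pytest

from lunggrade import synthetic
from lunggrade.types import GradeMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_slide():
    """One reproducible synthetic slide (image + label mask)."""
    spec = synthetic.random_slide_spec(7, canvas_size=(320, 320), n_tumors=4, tumor_radius=(30, 50))
    rgb, labels = synthetic.make_synthetic_slide(spec)
    return spec, rgb, labels


@pytest.fixture(scope="session")
def small_grade_map(small_slide):
    _, _, labels = small_slide
    return GradeMap(labels=labels)
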
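import numpy as np
import pytest

from lvind import PhantomSpec, ReferenceRange, generate_phantom
from lvind.contours import LaxContour, Phase, View
from lvind.phantom import _half_ellipse


@pytest.fixture(scope="session")
def reference():
    return ReferenceRange.packaged()


@pytest.fixture(scope="session")
def paired_phantom():
    """Uniform-contraction paired phantom (s = 0.33) with its truth."""
    return generate_phantom(PhantomSpec(contraction=0.33, mode="paired", seed=11))


@pytest.fixture(scope="session")
def half_ellipse_contour():
    """Dense ED half-ellipse: equatorial radius 20 mm, length 90 mm."""
    pts = _half_ellipse(20.0, 90.0, 1001)
    return LaxContour(View.CH2, Phase.ED, pts)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
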
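import numpy as np
import pytest

from cortexshape import synthetic_scenes as ss
from cortexshape.contour_shape import MembraneContour


@pytest.fixture(scope="session")
def circle_contour():
    return ss.contour_from_modes(20.0, {})


@pytest.fixture(scope="session")
def square_contour():
    t = np.linspace(0, 1, 90, endpoint=False)
    side = 20.0
    corners = [(0, 0), (1, 0), (1, 1), (0, 1)]
    pts = []
    for (x0, y0), (x1, y1) in zip(corners, corners[1:] + corners[:1]):
        pts.append(np.column_stack([x0 + (x1 - x0) * t,
                                    y0 + (y1 - y0) * t]) * side)
    return MembraneContour(np.vstack(pts))


@pytest.fixture(scope="session")
def rendered_circle():
    """Noise-free two-channel rendering of a 12 um liposome (h = 0.3 um)."""
    contour = ss.contour_from_modes(12.0, {})
    memb, act, truth = ss.render_two_channel_frame(
        contour, 0.3, 0.119, None, None, 0.0938)
    return contour, memb, act, truth


@pytest.fixture(scope="session")
def rendered_circle_noisy():
    contour = ss.contour_from_modes(12.0, {})
    memb, act, truth = ss.render_two_channel_frame(
        contour, 0.29, 0.119, None, ss.PoissonGaussianNoise(), 0.0938, seed=11)
    return contour, memb, act, truth
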
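import numpy as np
import pytest

import guvkit as g

PX = 0.2  # um/px used throughout the tests


@pytest.fixture(scope="session")
def px():
    return PX


@pytest.fixture(scope="session")
def plain_guv_frame():
    """Noise-free homogeneous 20 um GUV, no actin."""
    spec = g.SynthSpec(guv_diameter_um=20.0, pixel_size_um=PX)
    return g.render_guv_frame(spec)


@pytest.fixture(scope="session")
def shell_frame():
    """Noise-free 20 um GUV with a 5 um symmetric actin shell."""
    spec = g.SynthSpec(guv_diameter_um=20.0, pixel_size_um=PX,
                       actin_structure="symmetric_shell", actin_thickness_um=5.0)
    return g.render_guv_frame(spec)


def circle_contour(radius_px: float, center=(0.0, 0.0), n=720, pixel_size_um=PX):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius_px * np.cos(th),
                           center[1] + radius_px * np.sin(th)])
    return g.GuvContour(vertices=pts, pixel_size_um=pixel_size_um)
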
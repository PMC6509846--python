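import numpy as np
import pytest

from pigmentpattern.synth import ShapeSpec, render_shapes


@pytest.fixture(scope="session")
def disc_scene():
    """Disc radius 10 on a 32x32 canvas, rendered at 256x256 px."""
    return render_shapes([ShapeSpec("disc", (16, 16), radius=10)],
                         canvas=(32, 32), resolution=8)


@pytest.fixture(scope="session")
def square_scene():
    """10x10 square on a 32x32 canvas, rendered at 256x256 px."""
    return render_shapes([ShapeSpec("rectangle", (16, 16), width=10, height=10)],
                         canvas=(32, 32), resolution=8)


@pytest.fixture(scope="session")
def equal_area_scene():
    """Disc area 100*pi next to a square of the same area (equal weights)."""
    side = np.sqrt(100 * np.pi)
    return render_shapes([ShapeSpec("disc", (30, 50), radius=10),
                          ShapeSpec("rectangle", (70, 50),
                                    width=side, height=side)],
                         canvas=(100, 100), resolution=8)
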
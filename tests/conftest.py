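import numpy as np
import pytest

from ntpipe.optics import OpticsModel
from ntpipe.render import render_scene
from ntpipe.scene import Tube, VolumeScene


@pytest.fixture(scope="session")
def optics():
    """Default noise-free optics: 460 nm PSF, 1.2 um sheet, 105 nm pixels,
    0.4 um steps at 45 degrees."""
    return OpticsModel()


@pytest.fixture(scope="session")
def straight_tube_volume(optics):
    """A 10 um sub-resolution tube along x, rendered noise-free, with its
    endpoint seeds."""
    a = np.array([1.0, 2.0, 1.25])
    b = np.array([11.0, 2.0, 1.25])
    scene = VolumeScene(
        tubes=[Tube(points=np.stack([a, b]), diameter_nm=100.0)],
        bounds=((0.0, 12.0), (0.0, 4.0), (0.0, 2.5)),
    )
    return render_scene(scene, optics), a, b
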
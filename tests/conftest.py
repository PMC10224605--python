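import numpy as np
import pytest

from leaflux.scene import CameraModel, Layout, make_illumination, make_scene, render


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def small_layout() -> Layout:
    """Compact field geometry that keeps unit tests fast."""
    return Layout(height=160, width=160, panel_size_px=12, margin_px=6, plant_radius_px=8)


@pytest.fixture(scope="session")
def small_scene(small_layout):
    return make_scene(12, small_layout, seed=7)


@pytest.fixture(scope="session")
def sunny_frame(small_scene, camera):
    illum = make_illumination("sunny", small_scene.shape, seed=0)
    return render(small_scene, illum, camera)
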
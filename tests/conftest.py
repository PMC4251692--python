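import numpy as np
import pytest

from veinviz.camera import CameraSettings
from veinviz.enhance import EnhanceConfig, process_frame
from veinviz.image import NIRImage
from veinviz.phantom import PhantomSpec, VeinSegment, render_phantom


def straight_vein(spec: PhantomSpec, depth: float, radius: float = 1.0) -> VeinSegment:
    """Horizontal vein across the middle of the field, 2 mm end margins."""
    h_mm, w_mm = spec.field_of_view_mm
    return VeinSegment(
        centerline=np.array([[h_mm / 2, 2.0], [h_mm / 2, w_mm - 2.0]]),
        radius=radius,
        depth=depth,
    )


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def single_vein_phantom(default_spec):
    """Default phantom with one straight vein at 2 mm depth, noise 0.01."""
    return render_phantom(default_spec, [straight_vein(default_spec, depth=2.0)])


@pytest.fixture(scope="session")
def enhanced_single_vein(single_vein_phantom):
    return process_frame(
        single_vein_phantom.image, CameraSettings(), EnhanceConfig.for_mode("dog1")
    )


@pytest.fixture
def ramp_image() -> NIRImage:
    r = np.linspace(0.0, 1.0, 100)
    return NIRImage(np.tile(r, (100, 1)), pixel_pitch=0.1)


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """One synthetic study bundle shared across tests (seeded)."""
    from veinviz.fixtures import make_fixtures

    out = tmp_path_factory.mktemp("bundle")
    summary = make_fixtures(seed=42, out_dir=out)
    return out, summary
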
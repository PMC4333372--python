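import numpy as np
import pytest

import astigtrack as at


@pytest.fixture(scope="session")
def psf():
    return at.PsfModel()


@pytest.fixture(scope="session")
def cam():
    return at.CameraModel()


@pytest.fixture(scope="session")
def clean_stack(psf, cam):
    """Noise-free high-photon calibration stack, -1..+1 µm in 50 nm steps."""
    stack, z = at.render_calibration_stack(psf, cam, -1.0, 1.0, 0.05, photons=5000.0, noise=False)
    return stack, z


@pytest.fixture(scope="session")
def templates(clean_stack):
    stack, z = clean_stack
    return at.extract_templates(stack, z, offset=0.4, size=11)


@pytest.fixture(scope="session")
def curve(clean_stack, templates):
    stack, z = clean_stack
    t1, t2 = templates
    return at.fit_calibration(stack, z, t1, t2)


def render_spot(psf, cam, z_rel, photons, shape=(32, 32), noise=False, rng=None, offset_px=(0.0, 0.0)):
    """One emitter at the centre pixel (plus optional sub-pixel offset)."""
    ny, nx = shape
    x = (nx // 2 + 0.5 + offset_px[0]) * cam.pixel_size
    y = (ny // 2 + 0.5 + offset_px[1]) * cam.pixel_size
    return at.render_frame([(x, y, z_rel, photons)], psf, cam, shape, noise=noise, rng=rng)
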
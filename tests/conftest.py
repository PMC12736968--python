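
import numpy as np
import pytest

from made import MotionParameters, PSFSpec, render_object_trail


@pytest.fixture(scope="session")
def default_psf():
    return PSFSpec()


@pytest.fixture(scope="session")
def delta_psf():
    return PSFSpec(kind="delta")


def frame_for(trail_px: float, phi: float, **kwargs):
    """Object-trail frame with a given drift length in pixels (T = 1 s)."""
    params = MotionParameters(v=trail_px / 125.0, phi=phi)
    return render_object_trail(params, kwargs.pop("psf", PSFSpec()), **kwargs)


@pytest.fixture(scope="session")
def moving_frame():
    """A well-conditioned blurred frame (30 px trail at 30 degrees)."""
    return frame_for(30, 30)


@pytest.fixture(scope="session")
def static_frame():
    """A sharp, motionless disk on white."""
    params = MotionParameters(A=0.0, omega=0.0, v=0.0, phi=0.0)
    return render_object_trail(params, PSFSpec(), object_radius=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
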
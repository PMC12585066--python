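import pytest

from scmospia import CameraParams


@pytest.fixture(scope="session")
def chip() -> CameraParams:
    """Calibrated chip parameters of the reference sCMOS camera
    (balanced gain mode)."""
    return CameraParams(gain=0.81, tl_shape=0.055, tl_scale=1.310, offset=100.10)


@pytest.fixture(scope="session")
def poisson_chip() -> CameraParams:
    """Degenerate camera: unit gain, no read noise, no offset — the image
    count then reduces to the Poisson photoelectron count."""
    return CameraParams(gain=1.0, tl_shape=0.14, tl_scale=0.0, offset=0.0)
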
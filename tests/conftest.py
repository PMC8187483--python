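import numpy as np
import pytest

from thermoflow import make_face_scene, simulate_thermal_video


@pytest.fixture(scope="session")
def scene():
    return make_face_scene(seed=11)


@pytest.fixture(scope="session")
def clean_video(scene):
    """Motion-free video at the camera noise floor."""
    return simulate_thermal_video(scene=scene, T=240, seed=11, motion_amplitude=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def ar1(rng, n, phi=0.9, size=None, burn=300):
    """Independent stationary AR(1) series (rows) for null-calibration
    tests; a burn-in discards the zero-start transient."""
    from scipy.signal import lfilter

    shape = (n + burn,) if size is None else (size, n + burn)
    e = rng.standard_normal(shape)
    x = lfilter([1.0], [1.0, -phi], e, axis=-1)
    return x[..., burn:]
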
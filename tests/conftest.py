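"""Shared fixtures: phantom scenes and small-frame analysis windows.

The default phantom geometry is 96×96×32, so the paper-scale smoothing
windows are scaled down accordingly: a 15×15 plane median for the 3D method
and a 9×9 structuring element for conditional morphology (the library
defaults, 29×29 and 17×17, target ~700×520 frames).
"""

import numpy as np
import pytest

from hsseg import preprocess, synth
from hsseg.conditional_morphology import MorphParams

# frame-scaled analysis windows for the 96x96 phantom geometry
TEST_MORPH = MorphParams(mask_rows=9, mask_cols=9, p_ec=0.5, p_dc=0.5)
TEST_PLANE_WINDOW = 15


@pytest.fixture(scope="session")
def default_phantom():
    """Moderate-noise default scene (one elliptical object), fixed seed."""
    return synth.render_phantom(synth.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def calibrated_cube(default_phantom):
    """The default phantom after 3x3x3 median filtering + dark/white calibration."""
    ph = default_phantom
    return preprocess.standard_pipeline(ph.raw, ph.dark, ph.white)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Zero-noise, artifact-free scene for exactness checks."""
    return synth.render_phantom(
        synth.PhantomSpec(seed=1, noise_sigma_mid=0.0, noise_edge_gain=1.0, artifact_count=0)
    )


@pytest.fixture(scope="session")
def noiseless_calibrated(noiseless_phantom):
    ph = noiseless_phantom
    return preprocess.calibrate(ph.raw, ph.dark, ph.white)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
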
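import numpy as np
import pytest

import viafit as vf


@pytest.fixture(scope="session")
def blob_img():
    return vf.generate_blob_image(width=64, height=64, n_blobs=6, seed=7)


@pytest.fixture(scope="session")
def small_domain(blob_img):
    """(alpha0, grid) on a 16x16 node grid from the blob fixture."""
    return vf.image_to_alpha0(blob_img, nx=16, ny=16)


@pytest.fixture(scope="session")
def sim_config():
    return vf.SimConfig()


@pytest.fixture(scope="session")
def treatment_truth():
    """Partial-response treatment with oxygen decoupled (C = 1)."""
    return vf.default_treatment_params().replace(Q=0.0, Q1=0.0)


@pytest.fixture(scope="session")
def control_truth():
    return vf.default_control_params()
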
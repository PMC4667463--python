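import numpy as np
import pytest

from poolblend.design import build_model_matrices
from poolblend.designs import mouse_design, small_pooled_design
from poolblend._batch import reduce_design


@pytest.fixture(scope="session")
def mouse_mats():
    return build_model_matrices(mouse_design(), "individual")


@pytest.fixture(scope="session")
def mouse_red(mouse_mats):
    return reduce_design(mouse_mats)


@pytest.fixture(scope="session")
def small_mats():
    return build_model_matrices(small_pooled_design())


def gaussian_transcripts(mats, sigma1, sigma2, sigma_e, m, seed, mean=10.0):
    """Draw transcripts directly from the Gaussian mixed model."""
    n = mats.n
    V = sigma1 * (mats.Z1 @ mats.G1 @ mats.Z1.T) + sigma_e * np.eye(n)
    if sigma2:
        V = V + sigma2 * (mats.Z2 @ mats.G2 @ mats.Z2.T)
    L = np.linalg.cholesky(V)
    rng = np.random.default_rng(seed)
    return mean + rng.standard_normal((m, n)) @ L.T


@pytest.fixture(scope="session")
def mouse_truth_vc():
    """Model-scale components implied by the default calibration."""
    s1 = float(np.exp(0.103) - 1.0)
    return {"sigma1": s1, "sigma2": s1 * 2.7, "sigma_e": 0.017}
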
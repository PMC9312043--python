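import numpy as np
import pytest

from msadx.encoding import build_codebook, encode_cohort, fit_normalization
from msadx.pwl import PWLConfig
from msadx.synthcohort import CohortSpec, default_profiles, generate_cohort


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-case synthetic cohort, 420 cases, fixed seed."""
    spec = CohortSpec(n={"SND": 120, "SDS": 60, "OPCA": 240},
                      missingness_rate=0.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def matrix_b(small_cohort):
    cb = build_codebook("b")
    return encode_cohort(small_cohort, cb, fit_normalization(small_cohort, cb))


@pytest.fixture(scope="session")
def matrix_a(small_cohort):
    cb = build_codebook("a")
    return encode_cohort(small_cohort, cb, fit_normalization(small_cohort, cb))


@pytest.fixture
def tiny_cfg():
    """A small network that trains in seconds; for protocol/property tests."""
    return PWLConfig(n_epochs=25, n_inner_layers=2, layer_size=32,
                     learning_rate=1e-3, batch_size=64, seed=0)


@pytest.fixture
def blobs3():
    """Three well-separated Gaussian blobs in 2-D; linearly separable."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
    X = np.vstack([rng.normal(c, 0.5, size=(70, 2)) for c in centers])
    y = np.repeat([0, 1, 2], 70)
    return X, y
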
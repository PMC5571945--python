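import numpy as np
import pytest

from musclempi.phantom import PhantomParams, generate_timepoint


def small_params(**kw) -> PhantomParams:
    """Desk-scale phantom: fewer slices, default geometry otherwise."""
    kw.setdefault("grid_shape", (6, 64, 64))
    kw.setdefault("seed", 7)
    return PhantomParams(**kw)


def noiseless_params(**kw) -> PhantomParams:
    kw.setdefault("sigma_noise", 0.0)
    kw.setdefault("bias_amplitude", 0.0)
    kw.setdefault("misalign_mm", 0.0)
    kw.setdefault("misalign_deg", 0.0)
    kw.setdefault("beta_concentration", None)
    return small_params(**kw)


@pytest.fixture(scope="session")
def baseline_visit():
    """Default-noise baseline visit of one subject."""
    params = small_params()
    vol, msk, truth = generate_timepoint(params, 0.0)
    return params, vol, msk, truth


@pytest.fixture(scope="session")
def noiseless_visit():
    params = noiseless_params(f0_by_roi=0.3, rate_by_roi=0.0)
    vol, msk, truth = generate_timepoint(params, 0.0)
    return params, vol, msk, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
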
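import pytest

import dcquant


@pytest.fixture(scope="session")
def quiet_nucleus():
    """One noise-free wild-type-like nucleus with its ground truth."""
    params = dcquant.preset("wt-like", noise_scale=0.0, seed=3)
    dapi, sig, truth = dcquant.generate_nucleus_stack(params)
    return params, dapi, sig, truth


@pytest.fixture(scope="session")
def noisy_nucleus():
    """One default-noise wild-type-like nucleus with its ground truth."""
    params = dcquant.preset("wt-like", seed=7)
    dapi, sig, truth = dcquant.generate_nucleus_stack(params)
    return params, dapi, sig, truth
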
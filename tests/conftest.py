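import pytest

from hybridose import load_nuclide, phantom


@pytest.fixture(scope="session")
def tb161():
    return load_nuclide("Tb161")


@pytest.fixture(scope="session")
def lu177():
    return load_nuclide("Lu177")


@pytest.fixture()
def noiseless_spec():
    """Default phantom with all noise sources off."""
    return phantom.default_phantom_spec(
        "Tb161", seed=7, poisson_noise=False, spect_noise_sd=0.0)
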
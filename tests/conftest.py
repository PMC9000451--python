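import pytest

from enzybind.synthetic_data import AssayDesign, GroundTruth


@pytest.fixture
def design():
    """Default noiseless study layout."""
    return AssayDesign()


@pytest.fixture
def truth():
    """Default ground-truth parameter set."""
    return GroundTruth()


@pytest.fixture
def noisy_design():
    return AssayDesign(noise_sd=0.02, seed=7)
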
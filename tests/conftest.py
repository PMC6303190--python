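import numpy as np
import pytest

from metaconf.sdt import VariantParams
from metaconf.simulate import ObserverSpec, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def choice_bias_subject():
    """One simulated session from a choice-bias observer (ground truth known)."""
    observer = ObserverSpec(
        m=0.1, variant_params=VariantParams.choice_bias(0.6), miss_probability=0.0
    )
    calibration, trials = simulate_subject(observer, np.random.default_rng(11))
    return observer, calibration, trials


@pytest.fixture(scope="session")
def base_subject():
    """One simulated session from an ideal (base-model) observer."""
    observer = ObserverSpec(m=0.0, miss_probability=0.0)
    calibration, trials = simulate_subject(observer, np.random.default_rng(21))
    return observer, calibration, trials
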
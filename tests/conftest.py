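import numpy as np
import pytest

from ubiprom.seqfeat import PWM
from ubiprom.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def tbp_pwm() -> PWM:
    """A TBP-like TATA-box matrix (TATAAAAG consensus)."""
    probs = np.array(
        [
            [0.05, 0.05, 0.05, 0.85],
            [0.85, 0.05, 0.05, 0.05],
            [0.05, 0.05, 0.05, 0.85],
            [0.85, 0.05, 0.05, 0.05],
            [0.85, 0.05, 0.05, 0.05],
            [0.85, 0.05, 0.05, 0.05],
            [0.85, 0.05, 0.05, 0.05],
            [0.05, 0.05, 0.85, 0.05],
        ]
    )
    return PWM(probs, name="TBP-like")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11, n_elements=300, n_biosamples=40, n_genes=80)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
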
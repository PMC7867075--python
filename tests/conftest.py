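import numpy as np
import pytest

from bcgsleep.synthgen import SynthConfig, generate_feature_dataset
from bcgsleep.types import Recording


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_recording(rng):
    """30 s of white-noise 3-axis acceleration at 200 Hz."""
    n = 6000
    return Recording(
        subject_id="T", night_id="n", fs=200.0,
        ax=rng.normal(size=n), ay=rng.normal(size=n), az=rng.normal(size=n),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 1 night x 2 h: fast end-to-end material for unit tests."""
    tables, truths, gts = generate_feature_dataset(
        3, 1, SynthConfig(duration_h=2.0), seed=42
    )
    return tables, truths, gts


@pytest.fixture(scope="session")
def benchmark_dataset():
    """5 subjects x 2 nights at generator defaults (8 h): the study conditions."""
    tables, truths, gts = generate_feature_dataset(5, 2, SynthConfig(), seed=11)
    return tables, truths, gts
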
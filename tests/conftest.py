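import numpy as np
import pytest

from lnckit import synthetic


@pytest.fixture(scope="session")
def small_bundle():
    """Small labeled corpus with PWMs/bias tables for fast unit tests."""
    cfg = synthetic.GeneratorConfig(
        n_per_class=60, length_range=(200, 600), seed=7
    )
    return synthetic.gen_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), n))
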
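import numpy as np
import pytest

from multisub.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def cohort():
    """Well-separated 3-group multiomics cohort with survival signal."""
    cfg = SynthConfig(
        n_samples=300, k_true=3,
        omics_specs=[("meth", 6, 14), ("mrna", 6, 14)],
        separation=6.0, censor_rate=0.2, seed=2,
        hazard_scales=[200.0, 800.0, 2500.0])
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
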
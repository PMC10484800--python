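import numpy as np
import pytest

import petcorr as pc
from petcorr import experiment as exp


@pytest.fixture(scope="session")
def phantom_seed1():
    return pc.generate_phantom(pc.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def subject_noiseless():
    """One fully simulated phantom (noise off): µ-maps, PET pair, true map."""
    cfg = exp.ExperimentConfig(n_train=0, n_val=0, n_test=0,
                               recon={"noise": False})
    return exp.prepare_subject(pc.PhantomSpec(seed=42), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
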
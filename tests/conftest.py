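import numpy as np
import pytest

from soilflux import preprocessing as prep
from soilflux import synthetic as syn
from soilflux.flux import compute_fluxes

SIM_SEED = 20090101


@pytest.fixture(scope="session")
def sim270():
    """The reference 270-day hyperseasonal simulation (shared, read-only)."""
    profile, truth = syn.simulate(days=270, seed=SIM_SEED)
    return profile, truth


@pytest.fixture(scope="session")
def pre270(sim270):
    profile, _ = sim270
    pre, qc = prep.preprocess(profile)
    return pre, qc


@pytest.fixture(scope="session")
def flux270(pre270):
    pre, _ = pre270
    return compute_fluxes(pre, syn.truth_ds_model("10cm"),
                          syn.truth_ds_model("30cm"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
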
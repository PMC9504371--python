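import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from csfpbpk import ObservationDataset
from csfpbpk.model_core import CSFTransportParams
from csfpbpk.synthetic_data import (
    generate,
    sucrose_reference_design,
    sucrose_reference_spec,
)


@pytest.fixture(scope="session")
def sucrose_spec():
    return sucrose_reference_spec()


@pytest.fixture(scope="session")
def neutral_template(sucrose_spec):
    """The sucrose model with uninformative transport values (fit starting point)."""
    return sucrose_spec.model_copy(
        update={
            "transport": CSFTransportParams(
                venQ_D=1.0, cisQ_D=1.0, ud_ratio=1.0, sasQ=1.0, cf_ppa=1.0
            )
        }
    )


@pytest.fixture(scope="session")
def noiseless_sucrose_arms(sucrose_spec):
    """Noiseless flow-marker reference arms split into ICV and IC datasets."""
    ds = generate(sucrose_spec, sucrose_reference_design(noise_cv=0.0), seed=0)
    icv = ObservationDataset(drug="sucrose", arms=[ds.arm("icv")])
    ic = ObservationDataset(drug="sucrose", arms=[ds.arm("ic")])
    return icv, ic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
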
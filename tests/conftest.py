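import numpy as np
import pytest

from spheroct import (
    BScan,
    InstrumentSpec,
    SpheroidPhantom,
    SpheroidRIModel,
    simulate_bscan,
)


@pytest.fixture(scope="session")
def instrument():
    return InstrumentSpec()


@pytest.fixture(scope="session")
def noisy_instrument():
    return InstrumentSpec(speckle_contrast=0.3, noise_floor=20.0)


@pytest.fixture(scope="session")
def phantom():
    return SpheroidPhantom(n_s=1.38)


@pytest.fixture(scope="session")
def clean_bscan(phantom, instrument):
    img, gt = simulate_bscan(phantom, instrument, seed=1)
    return BScan(img, instrument), gt


@pytest.fixture(scope="session")
def clean_fit(clean_bscan):
    bscan, _ = clean_bscan
    return SpheroidRIModel(bscan).fit()
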
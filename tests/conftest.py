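import numpy as np
import pytest

from editquant import (
    AlleleMix,
    build_donor_vector,
    build_hdr_allele,
    build_nuclease_vector,
    build_synthetic_locus,
)
from editquant.lmu import build_element_panel


@pytest.fixture(scope="session")
def locus():
    return build_synthetic_locus(seed=7)


@pytest.fixture(scope="session")
def donor(locus):
    return build_donor_vector(locus, seed=8)


@pytest.fixture(scope="session")
def nuclease():
    return build_nuclease_vector(seed=9)


@pytest.fixture(scope="session")
def panel(locus, donor, nuclease):
    return build_element_panel(locus, donor, nuclease)


@pytest.fixture(scope="session")
def hdr_allele(locus, donor):
    return build_hdr_allele(locus, donor)


@pytest.fixture(scope="session")
def models(locus, donor, nuclease, panel):
    from editquant.workflows import StandardModels

    return StandardModels(locus, donor, nuclease, panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
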
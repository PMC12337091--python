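import numpy as np
import pytest

from forsternet.synthetic_data import (
    CP24_LIKE,
    LHC_MIMIC,
    make_toy_complex,
    make_toy_shift_table,
    make_toy_spectral_library,
)


@pytest.fixture(scope="session")
def study_complex():
    """Mixed-inventory toy complex (8 Chl a, 3 Chl b, 3 Crt), pinned seed."""
    return make_toy_complex(LHC_MIMIC)


@pytest.fixture(scope="session")
def library():
    return make_toy_spectral_library(LHC_MIMIC)


@pytest.fixture(scope="session")
def shifts():
    pigments, _ = make_toy_complex(LHC_MIMIC)
    return make_toy_shift_table(pigments, LHC_MIMIC.seed)


@pytest.fixture(scope="session")
def cp24_complex():
    """Chl-a-only worked-example inventory (11 Chl a, 3 Crt)."""
    return make_toy_complex(CP24_LIKE)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
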
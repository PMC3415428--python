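import numpy as np
import pytest

from amplocus import (
    generate_defensin_locus,
    generate_precursor_locus,
    hymenoptaecin_spec,
)
from amplocus.synthetic import DEFENSIN1_DIMS, DEFENSIN2_DIMS

#: fixed fixture seed; acceptance-script runs take theirs from the CLI
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def hym_spec():
    return hymenoptaecin_spec()


@pytest.fixture(scope="session")
def hym_bundle(hym_spec):
    return generate_precursor_locus(hym_spec, FIXTURE_SEED)


@pytest.fixture(scope="session")
def def1_bundle():
    return generate_defensin_locus(*DEFENSIN1_DIMS, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def def2_bundle():
    return generate_defensin_locus(*DEFENSIN2_DIMS, seed=FIXTURE_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)
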
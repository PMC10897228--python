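import warnings

import numpy as np
import pytest

from elfscan.synthetic import gen_complex_fixture, gen_proteome


@pytest.fixture(autouse=True)
def _quiet_geometry_warnings():
    """Fixture cages are residues without backbones; silence the expected warnings."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*lacks backbone atoms.*")
        warnings.filterwarnings("ignore", message=".*has no side chain.*")
        yield


@pytest.fixture(scope="session")
def full_fixture():
    """One complex fixture with every plantable feature, reused across tests."""
    return gen_complex_fixture(
        ("salt_bridge", "backbone_bridge", "beta_ladder", "insertion"), seed=1)


@pytest.fixture(scope="session")
def small_proteome():
    records, truth = gen_proteome(n_proteins=40, motif_literal="FADI",
                                  n_planted=4, seed=11)
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
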
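import numpy as np
import pytest

from corona_lab.nanobuilder import build_capped_np
from corona_lab.synthetic import (
    AdsorptionScenario,
    make_adsorption_trajectory,
    make_decoy_protein,
)


@pytest.fixture(scope="session")
def np_model():
    """Calibrated 314-atom core capped with 60 MUS ligands."""
    return build_capped_np(n_ligands=60, seed=1)


@pytest.fixture(scope="session")
def decoy_protein():
    """150-residue decoy globule used across analysis tests."""
    return make_decoy_protein(150, seed=3)


@pytest.fixture(scope="session")
def adsorption(np_model, decoy_protein):
    """One scripted three-phase adsorption run with known ground truth."""
    return make_adsorption_trajectory(
        decoy_protein, np_model, AdsorptionScenario(seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
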
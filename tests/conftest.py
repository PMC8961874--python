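import numpy as np
import pytest

from gdmr import pheno_sim


@pytest.fixture(scope="session")
def longitudinal_design():
    return pheno_sim.StudyDesign.default_longitudinal()


@pytest.fixture(scope="session")
def slaughter_design():
    return pheno_sim.StudyDesign.default_slaughter()


@pytest.fixture(scope="session")
def blood_effects():
    return pheno_sim.preset("blood_gdmr")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
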
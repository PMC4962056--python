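import numpy as np
import pytest

import hydrophi as hp
from hydrophi.synthetic_data import build_hairpin


@pytest.fixture(scope="session")
def helix():
    """12-residue ideal α-helix with Cβ side chains."""
    return hp.build_peptide(hp.PeptideSpec("KLVFFAEDVGSN", "alpha", seed=0))


@pytest.fixture(scope="session")
def hairpin():
    """14-residue hairpin native: the reference contact fixture."""
    return build_hairpin("KLVFFAEDVGSNKG", seed=0)


@pytest.fixture(scope="session")
def hairpin_contacts(hairpin):
    return hp.native_contacts(hairpin)


@pytest.fixture(scope="session")
def water_box_216():
    return hp.build_water_box(hp.WaterBoxSpec(216, box=1.86, seed=2))


@pytest.fixture(scope="session")
def solvated_peptide():
    """Small solvated tripeptide-scale system for hydration bookkeeping."""
    top, frame = hp.build_peptide(hp.PeptideSpec("AKLV", "ppii", seed=1))
    return hp.solvate((top, frame), hp.WaterBoxSpec(216, box=2.2, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
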
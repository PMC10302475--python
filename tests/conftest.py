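import numpy as np
import pytest

from nucsox.model_io import Atom, Structure
from nucsox.sequence_design import NucleotideSequence
from nucsox import synthetic_data as sd

TOY_SEQUENCE = "GCGCAAATTTGCGCGCAAATTTGCGCGCAAA"   # 31 nt, dyad at index 15


@pytest.fixture(scope="session")
def toy_duplex():
    return sd.build_bdna(NucleotideSequence(TOY_SEQUENCE, name="toy31"))


@pytest.fixture(scope="session")
def toy_duplex_map(toy_duplex):
    return sd.default_duplex_map(toy_duplex)


@pytest.fixture(scope="session")
def deformed_duplex(toy_duplex, toy_duplex_map):
    """Toy duplex widened to the 22.5 Å Sox-bound fingerprint at the dyad."""
    return sd.deform_groove(toy_duplex, center=0, span=12, target_width=22.5,
                            duplex_map=toy_duplex_map)


@pytest.fixture
def tiny_structure():
    """12 well-spread atoms on one pseudo-chain (superposable, non-planar)."""
    rng = np.random.default_rng(7)
    atoms = []
    for i, name in enumerate(("P", "C1'", "C2'") * 4):
        atoms.append(Atom(name, "DA", i // 3 + 1, "X", name[0],
                          rng.normal(scale=8.0, size=3)))
    return Structure(atoms, title="tiny")
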
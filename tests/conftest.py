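import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_structure(rng, n_residues, box=80.0, max_atoms=5, chain="A"):
    """Random multi-atom residue structure inside a cubic box (helper)."""
    from junctionmech.contacts import Residue, Structure

    residues = []
    for i in range(n_residues):
        center = rng.uniform(0, box, size=3)
        n_atoms = int(rng.integers(1, max_atoms + 1))
        atoms = center + rng.normal(scale=1.5, size=(n_atoms, 3))
        residues.append(Residue(chain=chain, index=i + 1, name="ALA", atoms=atoms))
    return Structure(residues=tuple(residues))
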
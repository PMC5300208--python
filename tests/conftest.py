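import numpy as np
import pytest

from gagmimic.topology import AtomRecord, Topology


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_chain_topology(n_atoms: int, element: str = "C") -> Topology:
    atoms = [
        AtomRecord(
            atom_index=i,
            atom_name=f"{element}{i + 1}",
            element=element,
            residue_name="CHN",
            residue_id=1,
        )
        for i in range(n_atoms)
    ]
    bonds = {frozenset((i, i + 1)) for i in range(n_atoms - 1)}
    return Topology(atoms=atoms, bonds=bonds)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
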
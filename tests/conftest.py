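import numpy as np
import pytest

from fcbind.structure_io import AtomRecord, StructureModel


def random_two_chain_model(seed: int, n_per_chain: int = 30, box: float = 15.0) -> StructureModel:
    """Random heavy-atom model with chains A and B packed in one box.

    Dense enough that 3 Å contacts occur by chance, for exercising the
    contact counter against the exhaustive oracle.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    for chain in ("A", "B"):
        coords = rng.uniform(0.0, box, size=(n_per_chain, 3))
        for i, p in enumerate(coords):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=f"C{i % 4 + 1}",
                    residue_name="ALA",
                    chain_id=chain,
                    residue_seq=i // 3 + 1,
                    x=float(p[0]),
                    y=float(p[1]),
                    z=float(p[2]),
                    element="C",
                )
            )
            serial += 1
    return StructureModel(1, atoms)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def tmp_pdb(tmp_path):
    return tmp_path / "model.pdb"
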
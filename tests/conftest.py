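import numpy as np
import pytest

from compdock.structures import AtomRecord, StructureModel


def make_structure(
    structure_id: str,
    residues: dict[int, dict[str, tuple[float, float, float]]],
    chain_id: str = "A",
    metadata: dict | None = None,
) -> StructureModel:
    """Build a StructureModel from {resnum: {atom_name: xyz}}."""
    atoms = [
        AtomRecord(
            atom_name=name,
            residue_number=resnum,
            insertion_code="",
            residue_name="ALA",
            chain_id=chain_id,
            position=np.asarray(xyz, dtype=float),
        )
        for resnum in sorted(residues)
        for name, xyz in residues[resnum].items()
    ]
    return StructureModel(structure_id, atoms, metadata or {})


@pytest.fixture
def toy_backbone():
    """Five-residue backbone with non-degenerate geometry."""
    rng = np.random.default_rng(42)
    residues = {}
    for i in range(1, 6):
        base = np.array([3.8 * i, 0.3 * i**2, 0.1 * i])
        residues[i] = {
            name: tuple(base + off + 0.05 * rng.normal(size=3))
            for name, off in zip(
                ("N", "CA", "C", "O"),
                ([0, 0, 0], [1.4, 0.3, 0], [2.4, -0.4, 0.8], [3.1, 0.5, 1.2]),
            )
        }
    return make_structure("TOY", residues)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
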
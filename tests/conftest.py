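import numpy as np
import pytest

from mqsar.structures import Atom, Molecule


@pytest.fixture
def water() -> Molecule:
    return Molecule(
        "water",
        [
            Atom("O", [0.0, 0.0, 0.0], atom_id=0),
            Atom("H", [0.9572, 0.0, 0.0], atom_id=1),
            Atom("H", [-0.2399, 0.9266, 0.0], atom_id=2),
        ],
        bonds=[(0, 1), (0, 2)],
    )


@pytest.fixture
def ethane() -> Molecule:
    atoms = [
        Atom("C", [0.0, 0.0, 0.0], atom_id=0),
        Atom("C", [1.54, 0.0, 0.0], atom_id=1),
    ]
    hs = [
        (-0.5, 0.9, 0.0), (-0.5, -0.45, 0.78), (-0.5, -0.45, -0.78),
        (2.04, 0.9, 0.0), (2.04, -0.45, 0.78), (2.04, -0.45, -0.78),
    ]
    for k, h in enumerate(hs):
        atoms.append(Atom("H", list(h), atom_id=2 + k))
    bonds = [(0, 1)] + [(0, i) for i in (2, 3, 4)] + [(1, i) for i in (5, 6, 7)]
    return Molecule("ethane", atoms, bonds)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based, det +1)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
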
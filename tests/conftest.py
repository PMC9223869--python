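import numpy as np
import pytest

from hatslens import Molecule
from hatslens import fixtures as fx

ELEMENTS = ("H", "C", "N", "O", "F", "S", "Cl", "Br")


def random_molecule(rng: np.random.Generator, max_atoms: int = 30, min_atoms: int = 4) -> Molecule:
    """Random connected molecule-like graph with random 3D coordinates.

    A spanning tree plus a few extra edges; geometry is random (no chemistry),
    which is exactly what oracle-equivalence and invariant checks need.
    """
    n = int(rng.integers(min_atoms, max_atoms + 1))
    symbols = tuple(rng.choice(ELEMENTS, size=n))
    coords = rng.uniform(-5.0, 5.0, size=(n, 3))
    bonds = {(int(rng.integers(1, i)), i) for i in range(2, n + 1)}
    for _ in range(int(rng.integers(0, n // 3 + 1))):
        i, j = rng.integers(1, n + 1, size=2)
        if i != j:
            bonds.add((min(int(i), int(j)), max(int(i), int(j))))
    return Molecule(symbols=symbols, coords=coords, bonds=frozenset(bonds), name=f"rand{n}")


def random_rigid_transform(rng: np.random.Generator):
    """Random proper rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-10, 10, size=3)
    return Q, t


@pytest.fixture(scope="session")
def c60():
    return fx.make_fullerene_c60()


@pytest.fixture(scope="session")
def icosane():
    return fx.make_n_alkane(20)


@pytest.fixture(scope="session")
def hbc():
    return fx.make_hexabenzocoronene()


@pytest.fixture(scope="session")
def methane():
    return fx.make_methane()


@pytest.fixture(scope="session")
def chlorobenzene():
    return fx.make_chlorobenzene()
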
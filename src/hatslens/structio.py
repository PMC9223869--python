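"""Structure I/O: SDF/MOL/XYZ reading, bond perception, fragment files, PDB export.

All atom indices visible to users (bond pairs, fragment partitions, reports)
are 1-based, following the SDF/MOL convention.  Coordinates are Cartesian
Angstrom.  HATS descriptors are defined on explicit-hydrogen structures, so a
structure with more than one heavy atom and no hydrogens triggers a warning
(computation still proceeds: the math is well defined either way).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .weights import covalent_radius

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "FragmentPartition",
    "StructureError",
    "StructureParseError",
    "EmptyStructureError",
    "read_structure",
    "write_sdf",
    "perceive_bonds",
    "read_fragment_partition",
    "write_leverage_pdb",
]


class StructureError(ValueError):
    """Base class for structure input problems."""


class StructureParseError(StructureError):
    """A file could not be parsed in the declared dialect."""


class EmptyStructureError(StructureError):
    """A record contained zero atoms."""


@dataclass(frozen=True)
class Molecule:
    """An explicit-hydrogen 3D structure.

    Parameters
    ----------
    symbols
        Element symbols in file order (index 1 = first atom).
    coords
        ``(A, 3)`` Cartesian coordinates in Angstrom.
    bonds
        Unordered 1-based atom-index pairs.  Bond order is not stored: the
        molecular graph alone enters the topological distance matrix.
    name
        Free-text title.
    """

    symbols: tuple[str, ...]
    coords: np.ndarray
    bonds: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    name: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise StructureError(f"coords must be (A, 3), got {coords.shape}")
        if len(self.symbols) != coords.shape[0]:
            raise StructureError(
                f"{len(self.symbols)} symbols but {coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] == 0:
            raise EmptyStructureError("structure has zero atoms")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        norm = set()
        a = self.n_atoms
        for bond in self.bonds:
            i, j = bond
            if i == j:
                raise StructureError(f"self-bond on atom {i}")
            if not (1 <= i <= a and 1 <= j <= a):
                raise StructureError(f"bond ({i}, {j}) outside 1..{a}")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "bonds", frozenset(norm))

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def explicit_h(self) -> bool:
        """True when at least one H is present or there is a single heavy atom."""
        return "H" in self.symbols or self.n_atoms == 1

    def with_bonds(self, bonds: Iterable[tuple[int, int]]) -> "Molecule":
        return replace(self, bonds=frozenset(bonds))

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return replace(self, coords=np.array(coords, dtype=float))


@dataclass(frozen=True)
class FragmentPartition:
    """Total assignment of 1-based atom indices to fragment labels.

    Fragments are user-defined chemistry (a common core, substituents R1..R4,
    ...); every atom belongs to exactly one fragment.
    """

    assignment: Mapping[int, str]

    def __post_init__(self) -> None:
        assignment = dict(self.assignment)
        if not assignment:
            raise StructureError("empty fragment partition")
        object.__setattr__(self, "assignment", assignment)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.assignment.values())))

    def label_of(self, atom_index: int) -> str:
        return self.assignment[atom_index]

    def validate_against(self, mol: Molecule) -> None:
        atoms = set(range(1, mol.n_atoms + 1))
        assigned = set(self.assignment)
        missing = sorted(atoms - assigned)
        if missing:
            raise StructureError(f"partition misses atoms {missing}")
        extra = sorted(assigned - atoms)
        if extra:
            raise StructureError(f"partition indexes non-existent atoms {extra}")


def _check_explicit_h(mol: Molecule) -> None:
    heavy = sum(1 for s in mol.symbols if s != "H")
    if heavy > 1 and "H" not in mol.symbols:
        warnings.warn(
            f"structure '{mol.name or '?'}' has {heavy} heavy atoms and no "
            "hydrogens; HATS descriptors are defined for explicit-hydrogen "
            "structures",
            UserWarning,
            stacklevel=3,
        )


def _from_rdkit(rdmol: Chem.Mol, record: int, path: str) -> Molecule:
    if rdmol.GetNumAtoms() == 0:
        raise EmptyStructureError(f"{path}: record {record} has zero atoms")
    if rdmol.GetNumConformers() == 0:
        raise StructureParseError(f"{path}: record {record} has no coordinates")
    conf = rdmol.GetConformer()
    symbols = tuple(a.GetSymbol() for a in rdmol.GetAtoms())
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(rdmol.GetNumAtoms())]
    )
    bonds = frozenset(
        (b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1) for b in rdmol.GetBonds()
    )
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    return Molecule(symbols=symbols, coords=coords, bonds=bonds, name=name)


def _read_sdf(path: Path) -> list[Molecule]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols: list[Molecule] = []
    for rec, rdmol in enumerate(supplier, start=1):
        if rdmol is None:
            raise StructureParseError(f"{path}: record {rec} failed to parse")
        mols.append(_from_rdkit(rdmol, rec, str(path)))
    if not mols:
        raise EmptyStructureError(f"{path}: no records")
    return mols


def _read_xyz(path: Path) -> Molecule:
    # Dialect: line 1 atom count, line 2 comment, then "element x y z".
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise StructureParseError(f"{path}: line 1 is not an atom count") from exc
    if n == 0:
        raise EmptyStructureError(f"{path}: zero atoms declared")
    if len(lines) < n + 2:
        raise StructureParseError(
            f"{path}: {n} atoms declared but file ends at line {len(lines)}"
        )
    symbols: list[str] = []
    rows: list[list[float]] = []
    for ln in range(2, 2 + n):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise StructureParseError(f"{path}: line {ln + 1} is not 'element x y z'")
        try:
            rows.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise StructureParseError(
                f"{path}: line {ln + 1} has a non-numeric coordinate"
            ) from exc
        symbols.append(parts[0])
    name = lines[1].strip()
    return Molecule(symbols=tuple(symbols), coords=np.array(rows), name=name)


def read_structure(
    path: str | Path, format: str = "auto"
) -> Molecule | list[Molecule]:
    """Read a structure file.

    ``format`` is one of ``sdf``, ``mol``, ``xyz`` or ``auto`` (by suffix).
    A single-record file yields one :class:`Molecule`; a multi-record SDF
    yields a list (atom order exactly as in the file, indices 1-based).  XYZ
    input has no bond block: call :func:`perceive_bonds` afterwards.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = {".sdf": "sdf", ".mol": "mol", ".xyz": "xyz"}.get(path.suffix.lower(), "sdf")
    if fmt in ("sdf", "mol"):
        mols = _read_sdf(path)
        for m in mols:
            _check_explicit_h(m)
        return mols[0] if len(mols) == 1 else mols
    if fmt == "xyz":
        mol = _read_xyz(path)
        _check_explicit_h(mol)
        return mol
    raise ValueError(f"unknown format {format!r}")


def _to_rdkit(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for sym in mol.symbols:
        atom = Chem.Atom(sym)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j in sorted(mol.bonds):
        rw.AddBond(i - 1, j - 1, Chem.BondType.SINGLE)
    conf = Chem.Conformer(mol.n_atoms)
    for i, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    out = rw.GetMol()
    out.AddConformer(conf)
    out.SetProp("_Name", mol.name)
    return out


def write_sdf(mols: Molecule | Sequence[Molecule], path: str | Path) -> None:
    """Write one or more molecules as a V2000 SDF (bond order written as 1)."""
    if isinstance(mols, Molecule):
        mols = [mols]
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for mol in mols:
        writer.write(_to_rdkit(mol))
    writer.close()


def perceive_bonds(mol: Molecule, scale: float = 1.15) -> Molecule:
    """Assign bonds from interatomic distances and covalent radii.

    Atoms ``i`` and ``j`` are bonded iff their Euclidean distance is at most
    ``scale * (r_cov(i) + r_cov(j))`` with Cordero single-bond covalent radii.
    Returns a new :class:`Molecule`; existing bonds are replaced.
    """
    radii = np.array([covalent_radius(s) for s in mol.symbols])
    diff = mol.coords[:, None, :] - mol.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cutoff = scale * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    return mol.with_bonds((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj))


def read_fragment_partition(path: str | Path, mol: Molecule) -> FragmentPartition:
    """Read a fragment partition (JSON object or two-column CSV).

    JSON maps 1-based atom index (as a string key) to a fragment label; CSV
    rows are ``atom_index,label``.  The partition must cover every atom of
    ``mol`` exactly once — no silent default fragment.
    """
    path = Path(path)
    text = path.read_text()
    pairs: list[tuple[int, str]] = []
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        raw = json.loads(text)
        if not isinstance(raw, dict):
            raise StructureParseError(f"{path}: JSON partition must be an object")
        for key, label in raw.items():
            pairs.append((int(key), str(label)))
    else:
        for row in csv.reader(text.splitlines()):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise StructureParseError(f"{path}: row {row!r} is not (index, label)")
            pairs.append((int(row[0]), row[1].strip()))
    assignment: dict[int, str] = {}
    for idx, label in pairs:
        if idx in assignment:
            raise StructureError(f"atom {idx} assigned twice")
        assignment[idx] = label
    part = FragmentPartition(assignment)
    part.validate_against(mol)
    return part


def write_leverage_pdb(mol: Molecule, leverages: Sequence[float]) -> str:
    """Encode per-atom leverages in PDB B-factors (leverage x 100, 2 decimals).

    The returned text colors by leverage in any molecular viewer
    ("spectrum b" in PyMOL); dividing the B-factor by 100 recovers the
    leverage to two decimals.
    """
    leverages = np.asarray(leverages, dtype=float)
    if leverages.size == 0:
        raise StructureError("empty leverage list")
    if leverages.size != mol.n_atoms:
        raise StructureError(
            f"{leverages.size} leverages for {mol.n_atoms} atoms"
        )
    lines = [f"COMPND    {mol.name or 'MOLECULE'}"]
    for idx, (sym, (x, y, z), h) in enumerate(
        zip(mol.symbols, mol.coords, leverages), start=1
    ):
        name = f"{sym}{idx}"[:4]
        lines.append(
            f"HETATM{idx:5d} {name:<4s} UNL A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{100.0 * h:6.2f}"
            f"          {sym:>2s}"
        )
    for i, j in sorted(mol.bonds):
        lines.append(f"CONECT{i:5d}{j:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
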
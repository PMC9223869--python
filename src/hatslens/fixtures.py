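"""Programmatic reference structures: fullerene, alkanes, PAHs, probes, conformers.

Everything the test-bench needs is generated from geometry, with no downloads
and no stochastic embedding: a truncated-icosahedron C60, all-anti n-alkanes,
planar hexa-peri-hexabenzocoronene (C42H18), benzene/chlorobenzene, a
fixed-geometry halide probe, and seeded synthetic conformer sets of an alkane
chain in linear / L / U shapes.

Geometries are idealized (standard bond lengths, exact tetrahedral or
trigonal angles).  Topological quantities (pair counts per lag) do not depend
on bond lengths at all, and the symmetric structures pin their leverages by
symmetry alone: icosahedral C60 forces every leverage to D/A = 3/60 exactly,
whatever the radius.
"""

from __future__ import annotations

import itertools
from math import cos, pi, radians, sin, sqrt

import numpy as np

from .structio import Molecule, perceive_bonds

__all__ = [
    "make_fullerene_c60",
    "make_n_alkane",
    "make_methane",
    "make_hexabenzocoronene",
    "make_benzene",
    "make_chlorobenzene",
    "make_halide_probe",
    "make_synthetic_conformers",
]

_PHI = (1.0 + sqrt(5.0)) / 2.0
CC_SINGLE = 1.54  # sp3 C-C, Angstrom
CC_AROM = 1.40  # aromatic C-C
CH = 1.09  # C-H
TET = 109.47122063449069  # tetrahedral angle, degrees


def _bonds_by_distance(coords: np.ndarray, cutoff: float) -> frozenset[tuple[int, int]]:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    return frozenset((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj))


def make_fullerene_c60() -> Molecule:
    """Buckminsterfullerene as a truncated icosahedron.

    Vertices are placed by truncating each icosahedron edge at the fraction
    that makes the hexagon-hexagon bonds 1.40 A and the pentagon (6:5) bonds
    1.46 A.  60 carbons, 90 bonds, every atom of degree 3; icosahedral
    symmetry makes all leverages equal (3/60 = 0.05).
    """
    b66, b65 = 1.40, 1.46
    edge_len = b66 + 2.0 * b65  # icosahedron edge so both bond lengths come out right
    t = b65 / edge_len  # truncation fraction along each directed edge
    # Icosahedron vertices: cyclic permutations of (0, +-1, +-phi), edge 2.
    base = []
    for s1, s2 in itertools.product((1, -1), repeat=2):
        v = (0.0, s1 * 1.0, s2 * _PHI)
        base.extend([v, (v[1], v[2], v[0]), (v[2], v[0], v[1])])
    ico = np.array(base) * (edge_len / 2.0)
    # Directed edges -> truncation points (one C60 vertex per directed edge).
    d2 = ((ico[:, None, :] - ico[None, :, :]) ** 2).sum(axis=-1)
    edge_sq = edge_len**2
    coords = []
    for a in range(12):
        for b in range(12):
            if a != b and abs(d2[a, b] - edge_sq) < 1e-6 * edge_sq:
                coords.append(ico[a] + t * (ico[b] - ico[a]))
    coords = np.array(coords)
    assert coords.shape == (60, 3)
    bonds = _bonds_by_distance(coords, 1.50)
    mol = Molecule(symbols=("C",) * 60, coords=coords, bonds=bonds, name="fullerene_C60")
    assert len(mol.bonds) == 90
    return mol


def _alkane_backbone(n: int, dihedrals: np.ndarray | None = None) -> np.ndarray:
    """Carbon backbone with C-C 1.54 A, tetrahedral angles, given dihedrals.

    ``dihedrals[i]`` (degrees) is the torsion C(i-2)-C(i-1)-C(i)-C(i+1) for
    atoms placed from index 3 on; 180 everywhere gives the all-anti zigzag.
    """
    theta = radians(TET)
    if n == 1:
        return np.zeros((1, 3))
    pos = [np.zeros(3), np.array([CC_SINGLE, 0.0, 0.0])]
    if n >= 3:
        pos.append(
            pos[1]
            + CC_SINGLE * np.array([cos(pi - theta), sin(pi - theta), 0.0])
        )
    if dihedrals is None:
        dihedrals = np.full(max(n - 3, 0), 180.0)
    for i in range(3, n):
        phi = radians(float(dihedrals[i - 3]))
        a, b, c = pos[i - 3], pos[i - 2], pos[i - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        nrm = np.cross(ab, bc)
        nrm /= np.linalg.norm(nrm)
        m = np.cross(nrm, bc)
        d2 = CC_SINGLE * sin(pi - theta)
        pos.append(
            c
            + CC_SINGLE * cos(pi - theta) * bc
            + d2 * (cos(phi) * m + sin(phi) * nrm)
        )
    return np.array(pos)


def _hydrogens_for_carbon(
    c: np.ndarray, neighbors: list[np.ndarray], n_h: int
) -> list[np.ndarray]:
    """Tetrahedral hydrogen positions completing a carbon's coordination."""
    cos_t = -1.0 / 3.0  # cos(109.47 deg)
    if len(neighbors) == 0:  # methane: ideal tetrahedron around c
        dirs = np.array(
            [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float
        ) / sqrt(3.0)
        return [c + CH * d for d in dirs[:n_h]]
    if len(neighbors) == 1:  # terminal CH3 (or CH2=... not used): staggered cap
        b = c - neighbors[0]
        b /= np.linalg.norm(b)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, b)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(b, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(b, e1)
        out = []
        for k in range(n_h):
            ang = 2.0 * pi * k / 3.0
            d = -cos_t * b + sqrt(1 - cos_t**2) * (cos(ang) * e1 + sin(ang) * e2)
            out.append(c + CH * d / np.linalg.norm(d))
        return out
    # interior CH2: both H at tetrahedral angle to both backbone bonds
    b1 = neighbors[0] - c
    b1 /= np.linalg.norm(b1)
    b2 = neighbors[1] - c
    b2 /= np.linalg.norm(b2)
    bis = b1 + b2
    bis /= np.linalg.norm(bis)
    nrm = np.cross(b1, b2)
    nrm /= np.linalg.norm(nrm)
    # solve d.b1 = d.b2 = cos_t with d = alpha*bis + beta*nrm
    alpha = cos_t / np.dot(bis, b1)
    beta = sqrt(max(1.0 - alpha**2, 0.0))
    out = []
    for s in (1.0, -1.0)[:n_h]:
        d = alpha * bis + s * beta * nrm
        out.append(c + CH * d / np.linalg.norm(d))
    return out


def _alkane_from_backbone(backbone: np.ndarray, name: str) -> Molecule:
    n = backbone.shape[0]
    symbols: list[str] = ["C"] * n
    coords: list[np.ndarray] = list(backbone)
    bonds = {(i, i + 1) for i in range(1, n)}
    for ci in range(n):
        nb = [backbone[ci - 1]] if ci > 0 else []
        if ci < n - 1:
            nb.append(backbone[ci + 1])
        n_h = 4 - len(nb)
        for h in _hydrogens_for_carbon(backbone[ci], nb, n_h):
            coords.append(h)
            symbols.append("H")
            bonds.add((ci + 1, len(coords)))
    return Molecule(
        symbols=tuple(symbols), coords=np.array(coords), bonds=frozenset(bonds), name=name
    )


def make_n_alkane(n_carbons: int, conformation: str = "all_anti") -> Molecule:
    """Unbranched alkane CnH2n+2 in the all-anti (fully extended) conformation."""
    if n_carbons < 1:
        raise ValueError("need at least one carbon")
    if conformation != "all_anti":
        raise ValueError(f"unknown conformation {conformation!r}")
    backbone = _alkane_backbone(n_carbons)
    return _alkane_from_backbone(backbone, name=f"n-C{n_carbons}H{2 * n_carbons + 2}")


def make_methane() -> Molecule:
    return make_n_alkane(1)


def make_hexabenzocoronene() -> Molecule:
    """Planar hexa-peri-hexabenzocoronene C42H18 on an ideal honeycomb lattice.

    13 fused hexagons (central + 6 ortho + 6 peri), C-C 1.42 A, 18 peripheral
    hydrogens, strictly z = 0 so the coordinate rank is exactly 2.
    """
    cc = 1.42
    centers = [np.zeros(2)]
    r1, r2 = sqrt(3.0) * cc, 3.0 * cc
    for k in range(6):
        ang = pi / 3.0 * k
        centers.append(r1 * np.array([cos(ang), sin(ang)]))
        ang2 = pi / 3.0 * k + pi / 6.0
        centers.append(r2 * np.array([cos(ang2), sin(ang2)]))
    verts: list[np.ndarray] = []
    for ctr in centers:
        for k in range(6):
            ang = pi / 3.0 * k + pi / 6.0
            v = ctr + cc * np.array([cos(ang), sin(ang)])
            if not any(np.linalg.norm(v - u) < 1e-6 for u in verts):
                verts.append(v)
    carbons = np.array([[x, y, 0.0] for x, y in verts])
    assert carbons.shape[0] == 42, carbons.shape
    bonds = set(
        (i, j) for i, j in _bonds_by_distance(carbons, cc * 1.05)
    )
    degree = {i: 0 for i in range(1, 43)}
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1
    coords = list(carbons)
    symbols = ["C"] * 42
    for ci in range(1, 43):
        if degree[ci] == 2:
            nbrs = [j for i, j in bonds if i == ci] + [i for i, j in bonds if j == ci]
            d = 2 * carbons[ci - 1] - carbons[nbrs[0] - 1] - carbons[nbrs[1] - 1]
            d /= np.linalg.norm(d)
            coords.append(carbons[ci - 1] + CH * d)
            symbols.append("H")
            bonds.add((ci, len(coords)))
    mol = Molecule(
        symbols=tuple(symbols),
        coords=np.array(coords),
        bonds=frozenset(bonds),
        name="hexabenzocoronene_C42H18",
    )
    assert mol.symbols.count("H") == 18, mol.symbols.count("H")
    return mol


def _ring_with_substituents(substituents: list[tuple[str, float]], name: str) -> Molecule:
    """Hexagonal C6 ring (C-C 1.40) with one radial substituent per carbon."""
    coords: list[list[float]] = []
    symbols: list[str] = []
    bonds: set[tuple[int, int]] = set()
    for k in range(6):
        ang = pi / 3.0 * k
        coords.append([CC_AROM * cos(ang), CC_AROM * sin(ang), 0.0])
        symbols.append("C")
    for i in range(6):
        bonds.add((i + 1, (i + 1) % 6 + 1))
    for k, (sym, length) in enumerate(substituents):
        ang = pi / 3.0 * k
        r = CC_AROM + length
        coords.append([r * cos(ang), r * sin(ang), 0.0])
        symbols.append(sym)
        bonds.add((k + 1, len(coords)))
    return Molecule(
        symbols=tuple(symbols), coords=np.array(coords), bonds=frozenset(bonds), name=name
    )


def make_benzene() -> Molecule:
    return _ring_with_substituents([("H", CH)] * 6, "benzene")


def make_chlorobenzene() -> Molecule:
    subs = [("Cl", 1.74)] + [("H", CH)] * 5
    return _ring_with_substituents(subs, "chlorobenzene")


def make_halide_probe(halogen: str) -> Molecule:
    """Para-substituted toluene-like scaffold with the halide site frozen.

    A benzene ring carries a methyl carbon at the para position and the probe
    substituent X (H, F, Cl or Br) at C1, 1.74 A away for *every* element, so
    the geometry — hence every leverage — is identical across the series and
    descriptor differences isolate the atomic weight.  X's single lag-5
    partner is the methyl carbon (X...ring...CH3 spans exactly five bonds),
    mirroring the halogen-carbon pairs that dominate mass-weighted values.
    Because the X position is frozen, bonds are set explicitly rather than
    perceived.
    """
    if halogen not in ("H", "F", "Cl", "Br"):
        raise ValueError(f"unsupported halogen {halogen!r}")
    subs = [(halogen, 1.74), ("H", CH), ("H", CH), ("C", 1.50), ("H", CH), ("H", CH)]
    mol = _ring_with_substituents(subs, f"halide_probe_{halogen}")
    methyl_idx = 10  # substituent on ring C4
    ring_c = mol.coords[3]
    hs = _hydrogens_for_carbon(mol.coords[methyl_idx - 1], [ring_c], 3)
    coords = np.vstack([mol.coords, np.array(hs)])
    symbols = mol.symbols + ("H",) * 3
    bonds = set(mol.bonds) | {(methyl_idx, 13), (methyl_idx, 14), (methyl_idx, 15)}
    return Molecule(
        symbols=symbols, coords=coords, bonds=frozenset(bonds), name=mol.name
    )


def _kink_positions(shape: str, n_dihedrals: int) -> tuple[int, ...]:
    if shape == "linear":
        return ()
    if shape == "l":  # one gauche kink pair mid-chain
        return (n_dihedrals // 2,)
    return (n_dihedrals // 4, 3 * n_dihedrals // 4)  # "u": two kink pairs


def make_synthetic_conformers(
    n_linear: int,
    n_u: int,
    n_l: int,
    seed: int,
    n_carbons: int = 12,
    jitter: float = 0.02,
) -> list[Molecule]:
    """Seeded conformer sets of one alkane chain in three planted shape classes.

    All conformers share the CnH2n+2 topology; shapes differ only in backbone
    dihedrals: all-anti (linear), one gauche kink pair mid-chain (L), two kink
    pairs (U, hairpin-like).  Small Gaussian coordinate jitter (sigma in
    Angstrom, default 0.02) makes replicates distinct but preserves class
    separation; the same seed reproduces coordinates bit-for-bit.
    """
    if n_carbons < 9:
        raise ValueError("need at least 9 carbons for distinct L and U kinks")
    rng = np.random.default_rng(seed)
    out: list[Molecule] = []
    for shape, count in (("linear", n_linear), ("u", n_u), ("l", n_l)):
        for rep in range(count):
            dihedrals = np.full(n_carbons - 3, 180.0)
            for pos in _kink_positions(shape, n_carbons - 3):
                dihedrals[pos] = 60.0
                dihedrals[min(pos + 1, n_carbons - 4)] = 60.0
            mol = _alkane_from_backbone(
                _alkane_backbone(n_carbons, dihedrals),
                name=f"{shape}_{rep + 1}",
            )
            if jitter > 0:
                mol = mol.with_coords(
                    mol.coords + rng.normal(0.0, jitter, size=mol.coords.shape)
                )
            out.append(mol)
    return out


def validate_fixture(mol: Molecule, scale: float = 1.15) -> bool:
    """Check that distance-based bond perception reproduces the intended graph."""
    return perceive_bonds(mol, scale=scale).bonds == mol.bonds
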
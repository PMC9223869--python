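"""Molecular Influence Matrix (MIM) and leverages.

The molecular matrix M holds the centered Cartesian coordinates (A rows, 3
columns; geometric center at the origin).  The MIM

    H = M (M^T M)^{-1} M^T

is the orthogonal projector onto the column space of M.  Its diagonal entries
h_ii — the leverages — measure how far atom i sits from the geometric center
relative to the whole spatial distribution: 0 <= h_ii <= 1, the leverages sum
to the rank D of M, and the mean leverage is D/A.  Because centering removes
translation and a projector is basis-independent within the column space, all
quantities are invariant to rigid motion.

The projector is computed from an SVD rather than the explicit inverse, so
exactly planar molecules (D = 2) and collinear ones (D = 1) — where M^T M is
singular — are handled with all invariants intact; the explicit inverse is the
full-rank special case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import Molecule

__all__ = [
    "MimResult",
    "center_coordinates",
    "molecular_influence_matrix",
    "mim_from_molecule",
    "leverage_table",
]


@dataclass(frozen=True)
class MimResult:
    """MIM projector, its diagonal (the leverages), and the coordinate rank."""

    H: np.ndarray
    leverages: np.ndarray
    rank_D: int

    @property
    def mean_leverage(self) -> float:
        return self.rank_D / self.leverages.size


def center_coordinates(mol: Molecule) -> np.ndarray:
    """Coordinates relative to the unweighted geometric center (column means 0)."""
    coords = np.asarray(mol.coords, dtype=float)
    return coords - coords.mean(axis=0)


def molecular_influence_matrix(M: np.ndarray, rank_tol: float = 1e-8) -> MimResult:
    """Projector onto the column space of the centered molecular matrix.

    Singular values below ``rank_tol`` times the largest are treated as zero.
    An all-zero M (single atom, or all atoms coincident) gives D = 0 and
    H = 0 — a documented degenerate case, not an error.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] != 3:
        raise ValueError(f"molecular matrix must be (A, 3), got {M.shape}")
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > rank_tol * s[0]
    else:
        keep = np.zeros_like(s, dtype=bool)
    rank = int(keep.sum())
    Ur = U[:, keep]
    H = Ur @ Ur.T
    H = (H + H.T) / 2.0  # enforce exact symmetry against fp round-off
    leverages = np.clip(np.diag(H).copy(), 0.0, 1.0)
    H.setflags(write=False)
    leverages.setflags(write=False)
    return MimResult(H=H, leverages=leverages, rank_D=rank)


def mim_from_molecule(mol: Molecule, rank_tol: float = 1e-8) -> MimResult:
    """Center the coordinates and build the MIM in one step."""
    return molecular_influence_matrix(center_coordinates(mol), rank_tol=rank_tol)


def leverage_table(mol: Molecule, mim: MimResult | None = None) -> pd.DataFrame:
    """Per-atom leverages as a DataFrame (atom index, element, leverage)."""
    if mim is None:
        mim = mim_from_molecule(mol)
    return pd.DataFrame(
        {
            "atom": range(1, mol.n_atoms + 1),
            "element": mol.symbols,
            "leverage": mim.leverages,
        }
    )
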
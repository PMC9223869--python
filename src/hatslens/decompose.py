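"""Substructure-based interpretation of HATS values.

Two complementary tools trace a descriptor value back to structural features:

* **Fragment decomposition** — with the molecule partitioned into fragments
  (a common core and substituents, say), every pair contribution is routed to
  the unordered fragment cell (frag(i), frag(j)).  Diagonal cells collect
  intra-fragment effects, off-diagonal cells the inter-fragment effects of the
  fragments' mutual spatial arrangement; the cells sum exactly to the
  descriptor value.

* **Substructure cutting** — atoms are deleted while the survivors keep their
  original coordinates (no capping, no re-optimization) and the whole pipeline
  is recomputed from scratch on the cut structure.  Leverages are global: the
  same moiety in a smaller molecule has different (larger, on average)
  leverages, so descriptors of a substructure are never sliced from the
  parent's pair list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hats import HatsResult, PairContribution, hats_profile
from .structio import FragmentPartition, Molecule
from .weights import SCHEME_IDS

__all__ = [
    "FragmentDecomposition",
    "fragment_decompose",
    "substructure_cut",
    "weighting_sensitivity",
    "decomposition_table",
]


@dataclass(frozen=True)
class FragmentDecomposition:
    """HATS value split over unordered fragment cells.

    ``matrix`` maps (label_a, label_b) with label_a <= label_b to the summed
    contribution; diagonal cells are intra-fragment.  ``pair_detail`` carries
    every contribution annotated with its fragment labels.
    """

    labels: tuple[str, ...]
    matrix: Mapping[tuple[str, str], float]
    total: float
    pair_detail: tuple[PairContribution, ...]
    lag: int
    scheme: str

    def cell(self, a: str, b: str) -> float:
        return self.matrix.get((min(a, b), max(a, b)), 0.0)

    def intra(self, label: str) -> float:
        return self.cell(label, label)

    def as_frame(self) -> pd.DataFrame:
        """Symmetric fragment x fragment contribution matrix."""
        n = len(self.labels)
        out = pd.DataFrame(
            np.zeros((n, n)), index=self.labels, columns=self.labels
        )
        for (a, b), v in self.matrix.items():
            out.loc[a, b] = v
            out.loc[b, a] = v
        return out


def fragment_decompose(
    result: HatsResult, lag: int, partition: FragmentPartition
) -> FragmentDecomposition:
    """Route every pair contribution at one lag to its fragment cell.

    HATS0 self terms land on the diagonal of their own fragment.  The cell
    sums are an exact partition of the descriptor's summands.
    """
    pairs = result.pairs[lag]
    matrix: dict[tuple[str, str], float] = {}
    detail: list[PairContribution] = []
    for p in pairs:
        fi = partition.label_of(p.i)
        fj = partition.label_of(p.j)
        key = (min(fi, fj), max(fi, fj))
        matrix[key] = matrix.get(key, 0.0) + p.value
        detail.append(p.with_fragments(fi, fj))
    return FragmentDecomposition(
        labels=partition.labels,
        matrix=matrix,
        total=result.values[lag],
        pair_detail=tuple(detail),
        lag=lag,
        scheme=result.scheme,
    )


def substructure_cut(
    mol: Molecule, keep: Sequence[int] | set[int]
) -> tuple[Molecule, dict[int, int]]:
    """Induced substructure on ``keep`` (1-based), original coordinates retained.

    Returns the cut molecule and the old-index -> new-index map.  No hydrogen
    capping and no re-centering happen here: centering is always recomputed as
    the first step of the MIM, so descriptors of the substructure reflect its
    own geometry-as-cut.
    """
    keep_sorted = sorted(set(int(i) for i in keep))
    if not keep_sorted:
        raise ValueError("keep set is empty")
    bad = [i for i in keep_sorted if not 1 <= i <= mol.n_atoms]
    if bad:
        raise ValueError(f"keep indices {bad} outside 1..{mol.n_atoms}")
    index_map = {old: new for new, old in enumerate(keep_sorted, start=1)}
    kept = set(keep_sorted)
    bonds = {
        (index_map[i], index_map[j])
        for i, j in mol.bonds
        if i in kept and j in kept
    }
    cut = Molecule(
        symbols=tuple(mol.symbols[i - 1] for i in keep_sorted),
        coords=mol.coords[[i - 1 for i in keep_sorted]],
        bonds=frozenset(bonds),
        name=f"{mol.name}|cut" if mol.name else "cut",
    )
    return cut, index_map


def weighting_sensitivity(
    mol: Molecule,
    partition: FragmentPartition,
    lag: int,
    schemes: Sequence[str] = SCHEME_IDS,
) -> pd.DataFrame:
    """Fragment-cell contributions per weighting scheme, aligned for comparison.

    Rows are schemes; columns are fragment cells labelled ``a`` (intra) or
    ``a~b`` (inter); a ``total`` column carries HATS(lag, scheme).
    """
    partition.validate_against(mol)
    results = hats_profile(mol, schemes=schemes, lags=(lag,))
    cells: set[tuple[str, str]] = set()
    decomps = {}
    for res in results:
        dec = fragment_decompose(res, lag, partition)
        decomps[res.scheme] = dec
        cells.update(dec.matrix)
    columns = ["~".join(dict.fromkeys(c)) for c in sorted(cells)]
    rows = {}
    for scheme, dec in decomps.items():
        row = {
            "~".join(dict.fromkeys(c)): dec.matrix.get(c, 0.0) for c in sorted(cells)
        }
        row["total"] = dec.total
        rows[scheme] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "scheme"
    return frame[columns + ["total"]]


def decomposition_table(dec: FragmentDecomposition, molecule: str = "") -> pd.DataFrame:
    """Long-format export: (molecule, scheme, lag, fragment_a, fragment_b, contribution)."""
    rows = [
        {
            "molecule": molecule,
            "scheme": dec.scheme,
            "lag": dec.lag,
            "fragment_a": a,
            "fragment_b": b,
            "contribution": v,
        }
        for (a, b), v in sorted(dec.matrix.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["molecule", "scheme", "lag", "fragment_a", "fragment_b", "contribution"],
    )
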
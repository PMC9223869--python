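"""Topological distances on the molecular graph and Dirac-delta pair selection.

The topological distance d_ij is the number of bonds on the shortest path
between atoms i and j — a purely graph-theoretic quantity, never Euclidean.
The Dirac delta δ(k; d_ij) keeps exactly the unordered pairs at lag k, the
pair set a HATS autocorrelation sums over.  Disconnected pairs (multi-fragment
input such as salts) get an infinite sentinel and never match any finite lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .structio import Molecule

__all__ = ["TopologyResult", "topological_distances", "dirac_select", "DEFAULT_LAGS"]

# Lags computed by default in batch profiles: HATS0 plus k = 1..8, the
# customary autocorrelation range.
DEFAULT_LAGS: tuple[int, ...] = tuple(range(0, 9))


@dataclass(frozen=True)
class TopologyResult:
    """All-pairs topological distance matrix.

    ``dist`` is an A x A float matrix: d_ii = 0, d_ij = 1 iff bonded,
    ``np.inf`` for disconnected pairs.  Positions are 0-based internally; the
    pair lists returned by :func:`dirac_select` are 1-based like all reports.
    ``n_pairs_at`` counts unordered pairs per finite lag k >= 1.
    """

    dist: np.ndarray
    n_pairs_at: dict[int, int]

    @property
    def n_atoms(self) -> int:
        return self.dist.shape[0]

    @property
    def diameter(self) -> int:
        finite = self.dist[np.isfinite(self.dist)]
        return int(finite.max()) if finite.size else 0


def topological_distances(mol: Molecule) -> TopologyResult:
    """Breadth-first shortest-path bond counts for every unordered atom pair."""
    a = mol.n_atoms
    if mol.bonds:
        idx = np.array([(i - 1, j - 1) for i, j in sorted(mol.bonds)])
        rows = np.concatenate([idx[:, 0], idx[:, 1]])
        cols = np.concatenate([idx[:, 1], idx[:, 0]])
        adj = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(a, a))
    else:
        adj = csr_matrix((a, a))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    dist.setflags(write=False)
    iu, ju = np.triu_indices(a, k=1)
    upper = dist[iu, ju]
    finite = upper[np.isfinite(upper)].astype(int)
    lags, counts = np.unique(finite, return_counts=True)
    n_pairs_at = {int(k): int(c) for k, c in zip(lags, counts)}
    return TopologyResult(dist=dist, n_pairs_at=n_pairs_at)


def dirac_select(topo: TopologyResult, k: int) -> list[tuple[int, int]]:
    """Unordered 1-based atom pairs (i < j) with d_ij exactly k, sorted by (i, j)."""
    if k < 1:
        raise ValueError(f"lag must be >= 1, got {k}")
    ii, jj = np.nonzero(np.triu(topo.dist == k, k=1))
    return [(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)]


def distance_frame(topo: TopologyResult):
    """Distance matrix as a DataFrame with 1-based labels (debug/CSV export)."""
    import pandas as pd

    labels = range(1, topo.n_atoms + 1)
    return pd.DataFrame(topo.dist, index=labels, columns=labels)
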
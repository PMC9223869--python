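"""Independent brute-force references used only by the test suite.

These deliberately avoid the package's own code paths: distances come from
networkx, leverages from the explicit normal-equations projector, HATS values
from a naive double loop over all atom pairs, and UPGMA from a quadratic
cluster-list agglomeration.
"""

import numpy as np
import networkx as nx

from hatslens.weights import atomic_weight


def nx_graph(mol):
    g = nx.Graph()
    g.add_nodes_from(range(1, mol.n_atoms + 1))
    g.add_edges_from(mol.bonds)
    return g


def floyd_warshall_distances(mol):
    """All-pairs distances via networkx Floyd-Warshall (inf when disconnected)."""
    g = nx_graph(mol)
    dist = np.full((mol.n_atoms, mol.n_atoms), np.inf)
    for i, row in nx.floyd_warshall(g).items():
        for j, d in row.items():
            dist[i - 1, j - 1] = d
    return dist


def explicit_inverse_leverages(mol):
    """Leverages from H = M (M^T M)^{-1} M^T with the literal inverse.

    Valid only for full-rank (genuinely 3D) geometries such as the random
    test molecules; this is the textbook formula, independent of the SVD path.
    """
    M = mol.coords - mol.coords.mean(axis=0)
    H = M @ np.linalg.inv(M.T @ M) @ M.T
    return np.diag(H)


def naive_hats(mol, scheme: str, k: int) -> float:
    """Direct double-loop evaluation of the HATS autocorrelation sums."""
    w = np.array([atomic_weight(scheme, s) for s in mol.symbols])
    h = explicit_inverse_leverages(mol)
    wh = w * h
    if k == 0:
        return float((wh**2).sum())
    d = floyd_warshall_distances(mol)
    a = mol.n_atoms
    total = 0.0
    for i in range(a):
        for j in range(i + 1, a):
            if d[i, j] == k:
                total += wh[i] * wh[j]
    return total


def brute_upgma_heights(dist_square: np.ndarray) -> list[float]:
    """Merge heights of average-linkage agglomeration, naive cluster lists."""
    n = dist_square.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([[dist_square[i, j] for j in clusters[b]] for i in clusters[a]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
    return heights
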
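"""Conformer shape analysis from pair-contribution fingerprints.

Conformers of one molecule share the bond graph, hence the same Dirac-delta
pair set at any lag; they differ only through their leverages (geometry).  The
vector of lag-k pair contributions is therefore a shape fingerprint on a pair
basis common to all conformers.  Fingerprints are compared by Euclidean
distance, clustered with UPGMA (average linkage), and the dendrogram's
faithfulness is summarized by the cophenetic correlation coefficient (CCC) —
the Pearson correlation between original and tree-implied distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .hats import hats_profile
from .structio import FragmentPartition, Molecule
from .topology import topological_distances

__all__ = [
    "PairFingerprint",
    "Dendrogram",
    "pair_fingerprints",
    "fingerprint_matrix",
    "upgma",
    "cophenetic_correlation",
    "shape_report",
    "to_newick",
]


@dataclass(frozen=True)
class PairFingerprint:
    """Lag-k pair contributions of one conformer on the shared pair basis."""

    conformer_id: str
    keys: tuple[tuple[int, int], ...]
    vector: np.ndarray

    @property
    def total(self) -> float:
        """Sum of entries = the conformer's HATS(k, scheme) value."""
        return float(self.vector.sum())


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree in SciPy linkage form plus cophenetic distances."""

    Z: np.ndarray
    leaf_ids: tuple[str, ...]
    cophenetic: np.ndarray  # condensed

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


def _check_shared_topology(conformers: Sequence[Molecule]) -> None:
    ref = conformers[0]
    for idx, mol in enumerate(conformers[1:], start=2):
        if mol.symbols != ref.symbols:
            raise ValueError(
                f"conformer {idx} element sequence differs from conformer 1"
            )
        if mol.bonds != ref.bonds:
            diff = sorted(mol.bonds ^ ref.bonds)[0]
            raise ValueError(
                f"conformer {idx} bond topology differs from conformer 1 "
                f"(first differing bond {diff})"
            )


def pair_fingerprints(
    conformers: Sequence[Molecule],
    lag: int = 5,
    scheme: str = "m",
    normalize: bool = False,
) -> list[PairFingerprint]:
    """Aligned pair-contribution vectors for conformers of one molecule.

    All conformers must share element sequence and bond set.  With
    ``normalize=True`` each vector is scaled to unit sum (shape only, size
    removed); the default keeps raw contributions so vector sums equal the
    HATS values.
    """
    if not conformers:
        raise ValueError("no conformers")
    _check_shared_topology(conformers)
    topo = topological_distances(conformers[0])
    keys: tuple[tuple[int, int], ...] | None = None
    out: list[PairFingerprint] = []
    for idx, mol in enumerate(conformers, start=1):
        (res,) = hats_profile(mol, schemes=(scheme,), lags=(lag,), topo=topo)
        pairs = sorted(res.pairs[lag], key=lambda p: (p.i, p.j))
        k = tuple((p.i, p.j) for p in pairs)
        if keys is None:
            keys = k
        vec = np.array([p.value for p in pairs])
        if normalize:
            total = vec.sum()
            if total > 0:
                vec = vec / total
        out.append(
            PairFingerprint(
                conformer_id=mol.name or f"conformer_{idx}", keys=keys, vector=vec
            )
        )
    return out


def fingerprint_matrix(fingerprints: Sequence[PairFingerprint]) -> np.ndarray:
    return np.vstack([fp.vector for fp in fingerprints])


def upgma(dist: np.ndarray, leaf_ids: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a condensed or square distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim == 2:
        dist = squareform(dist, checks=True)
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    n = int(round((1 + np.sqrt(1 + 8 * dist.size)) / 2))
    if n < 2:
        raise ValueError("need at least 2 observations")
    Z = linkage(dist, method="average")
    coph = cophenet(Z)
    ids = tuple(leaf_ids) if leaf_ids is not None else tuple(str(i + 1) for i in range(n))
    if len(ids) != n:
        raise ValueError(f"{len(ids)} leaf ids for {n} observations")
    return Dendrogram(Z=Z, leaf_ids=ids, cophenetic=coph)


def cophenetic_correlation(dend: Dendrogram, dist: np.ndarray) -> float:
    """Pearson correlation between original and cophenetic condensed distances."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim == 2:
        dist = squareform(dist, checks=True)
    if dist.size != dend.cophenetic.size:
        raise ValueError("distance matrix does not match the dendrogram leaf set")
    if dist.size < 2:
        raise ValueError("cophenetic correlation is undefined for fewer than 3 leaves")
    if np.ptp(dist) == 0 or np.ptp(dend.cophenetic) == 0:
        raise ValueError("cophenetic correlation undefined for zero-variance distances")
    return float(pearsonr(dist, dend.cophenetic)[0])


def shape_report(
    fingerprints: Sequence[PairFingerprint],
    n_clusters: int | None = None,
    height: float | None = None,
    partition: FragmentPartition | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Flat clusters plus a per-cluster mean profile for interpretation.

    Exactly one of ``n_clusters`` / ``height`` selects the cut.  The profile
    holds per-cluster means: total HATS value, and — when a fragment partition
    of the shared molecule is given — the mean contribution per fragment cell.
    """
    if (n_clusters is None) == (height is None):
        raise ValueError("pass exactly one of n_clusters or height")
    X = fingerprint_matrix(fingerprints)
    dist = pdist(X)
    dend = upgma(dist, leaf_ids=[fp.conformer_id for fp in fingerprints])
    if n_clusters is not None:
        if not 1 <= n_clusters <= len(fingerprints):
            raise ValueError(f"n_clusters must be in 1..{len(fingerprints)}")
        labels = fcluster(dend.Z, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(dend.Z, t=height, criterion="distance")
    assignments = pd.Series(
        labels, index=[fp.conformer_id for fp in fingerprints], name="cluster"
    )
    profile_cols = {"total": [fp.total for fp in fingerprints]}
    if partition is not None:
        keys = fingerprints[0].keys
        cells = sorted(
            {
                tuple(sorted((partition.label_of(i), partition.label_of(j))))
                for i, j in keys
            }
        )
        for cell in cells:
            mask = np.array(
                [
                    tuple(sorted((partition.label_of(i), partition.label_of(j)))) == cell
                    for i, j in keys
                ]
            )
            profile_cols["~".join(dict.fromkeys(cell))] = X[:, mask].sum(axis=1)
    per_conf = pd.DataFrame(profile_cols, index=assignments.index)
    profile = per_conf.groupby(assignments).mean()
    profile.index.name = "cluster"
    return assignments, profile


def _newick_node(node, leaf_ids: Sequence[str]) -> str:
    if node.is_leaf():
        return leaf_ids[node.id].replace(" ", "_")
    left = _newick_node(node.get_left(), leaf_ids)
    right = _newick_node(node.get_right(), leaf_ids)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.10g},{right}:{dr:.10g})"


def to_newick(dend: Dendrogram) -> str:
    """Dendrogram as a Newick string (ultrametric branch lengths)."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(dend.Z)
    return _newick_node(root, dend.leaf_ids) + ";"
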
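"""scikit-learn estimators over the descriptor pipeline.

`HATSFeaturizer` turns a list of molecules into a numeric feature matrix of
HATS(k, w) values — usable directly inside sklearn pipelines feeding QSAR
models.  `ConformerShapeClusterer` performs the fingerprint/UPGMA shape
analysis as a clusterer with the standard ``fit`` / ``fit_predict`` surface.
Both take lists of :class:`~hatslens.structio.Molecule` as X (like text
vectorizers take lists of strings), so the usual array validation is replaced
by structural checks.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from scipy.cluster.hierarchy import fcluster

from .hats import hats_profile
from .shapecluster import cophenetic_correlation, fingerprint_matrix, pair_fingerprints, upgma
from .structio import Molecule
from .topology import DEFAULT_LAGS
from .weights import SCHEME_IDS

__all__ = ["HATSFeaturizer", "ConformerShapeClusterer"]


def _check_molecules(X) -> list[Molecule]:
    mols = list(X)
    if not mols:
        raise ValueError("X is empty")
    bad = [i for i, m in enumerate(mols) if not isinstance(m, Molecule)]
    if bad:
        raise TypeError(f"X[{bad[0]}] is not a Molecule")
    missing = [i for i, m in enumerate(mols) if not m.bonds]
    if missing:
        raise ValueError(
            f"X[{missing[0]}] has no bonds; call perceive_bonds on XYZ input first"
        )
    return mols


class HATSFeaturizer(TransformerMixin, BaseEstimator):
    """Molecules -> matrix of HATS(k, w) descriptor values.

    Parameters
    ----------
    lags
        Lags to compute (0 = the squared self-term sum).
    schemes
        Weighting scheme ids among {u, m, v, e, p, i}.

    The transform is stateless; ``fit`` validates parameters and records the
    output feature names (``HATS{k}{w}``).
    """

    def __init__(
        self,
        lags: Sequence[int] = DEFAULT_LAGS,
        schemes: Sequence[str] = ("m",),
    ) -> None:
        self.lags = lags
        self.schemes = schemes

    def _validate_params(self) -> None:
        unknown = [s for s in self.schemes if s not in SCHEME_IDS]
        if unknown:
            raise ValueError(f"unknown schemes {unknown}; available {SCHEME_IDS}")
        if any(k < 0 for k in self.lags):
            raise ValueError("lags must be >= 0")

    def fit(self, X, y=None) -> "HATSFeaturizer":
        self._validate_params()
        _check_molecules(X)
        self.feature_names_out_ = np.array(
            [f"HATS{k}{s}" for s in self.schemes for k in self.lags], dtype=object
        )
        self.n_features_out_ = self.feature_names_out_.size
        return self

    def transform(self, X) -> np.ndarray:
        self._validate_params()
        mols = _check_molecules(X)
        rows = []
        for mol in mols:
            results = hats_profile(mol, schemes=tuple(self.schemes), lags=tuple(self.lags))
            rows.append([r.values[k] for r in results for k in self.lags])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self._validate_params()
            self.feature_names_out_ = np.array(
                [f"HATS{k}{s}" for s in self.schemes for k in self.lags], dtype=object
            )
        return self.feature_names_out_


class ConformerShapeClusterer(ClusterMixin, BaseEstimator):
    """UPGMA shape clustering of conformers on pair-contribution fingerprints.

    Parameters
    ----------
    n_clusters
        Flat-cut cluster count.
    lag, scheme
        Which HATS(k, w) pair contributions form the fingerprint.
    normalize
        Scale fingerprints to unit sum (compare shape only, not size).

    Attributes (after ``fit``)
    --------------------------
    labels_ : flat cluster labels (1..n_clusters)
    linkage_matrix_ : SciPy linkage array of the UPGMA tree
    cophenetic_correlation_ : CCC between input and tree distances
    fingerprints_ : the aligned pair-contribution matrix
    """

    def __init__(
        self,
        n_clusters: int = 3,
        lag: int = 5,
        scheme: str = "m",
        normalize: bool = False,
    ) -> None:
        self.n_clusters = n_clusters
        self.lag = lag
        self.scheme = scheme
        self.normalize = normalize

    def fit(self, X, y=None) -> "ConformerShapeClusterer":
        mols = _check_molecules(X)
        if not 1 <= self.n_clusters <= len(mols):
            raise ValueError(f"n_clusters must be in 1..{len(mols)}")
        fps = pair_fingerprints(
            mols, lag=self.lag, scheme=self.scheme, normalize=self.normalize
        )
        self.fingerprints_ = fingerprint_matrix(fps)
        self.pair_keys_ = fps[0].keys
        dist = pdist(self.fingerprints_)
        dend = upgma(dist, leaf_ids=[fp.conformer_id for fp in fps])
        self.dendrogram_ = dend
        self.linkage_matrix_ = dend.Z
        self.labels_ = fcluster(dend.Z, t=self.n_clusters, criterion="maxclust")
        try:
            self.cophenetic_correlation_ = cophenetic_correlation(dend, dist)
        except ValueError:
            self.cophenetic_correlation_ = float("nan")
        return self
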
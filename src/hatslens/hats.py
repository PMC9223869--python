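"""HATS leverage-weighted autocorrelation descriptors with per-pair bookkeeping.

For atomic weights w and leverages h (diagonal of the molecular influence
matrix):

    HATS0(w) = sum_i (w_i h_ii)^2
    HATSk(w) = sum_{i<j} (w_i h_ii)(w_j h_jj) delta(k; d_ij),   k = 1, 2, ...

where the Dirac delta keeps pairs at topological distance exactly k.  Unlike
descriptor engines that report only the final number, every summand is kept as
a :class:`PairContribution`, so a descriptor value can be traced to the atomic
pairs, weights and leverages that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mim import MimResult, mim_from_molecule
from .structio import Molecule
from .topology import DEFAULT_LAGS, TopologyResult, dirac_select, topological_distances
from .weights import weight_vector

__all__ = [
    "PairContribution",
    "HatsResult",
    "hats0",
    "hatsk",
    "hats_profile",
    "top_pairs_coverage",
    "hats_table",
]

# Relative slack absorbing floating-point summation error in coverage
# comparisons (e.g. many exactly-equal contributions summed in sequence).
_COVERAGE_RTOL = 1e-9


@dataclass(frozen=True)
class PairContribution:
    """One summand of a HATS value.

    ``i == j`` marks a HATS0 self term, whose value is the squared product
    (w_i h_ii)^2; for lag >= 1 the value is (w_i h_ii)(w_j h_jj) and
    d_ij = lag.  Indices are 1-based.  Fragment labels are attached by the
    decomposition stage.
    """

    i: int
    j: int
    lag: int
    value: float
    fragment_i: str | None = None
    fragment_j: str | None = None

    def with_fragments(self, fi: str, fj: str) -> "PairContribution":
        return replace(self, fragment_i=fi, fragment_j=fj)


@dataclass(frozen=True)
class HatsResult:
    """HATS values of one molecule under one weighting scheme, per lag."""

    name: str
    scheme: str
    values: Mapping[int, float]
    pairs: Mapping[int, tuple[PairContribution, ...]]
    leverages: np.ndarray = field(repr=False, default=None)

    def value(self, lag: int) -> float:
        return self.values[lag]

    @property
    def lags(self) -> tuple[int, ...]:
        return tuple(sorted(self.values))


def _validate(weights: Sequence[float], leverages: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(weights, dtype=float)
    h = np.asarray(leverages, dtype=float)
    if w.shape != h.shape or w.ndim != 1:
        raise ValueError(f"weights {w.shape} and leverages {h.shape} must be equal-length vectors")
    return w, h


def hats0(
    weights: Sequence[float], leverages: Sequence[float]
) -> tuple[float, list[PairContribution]]:
    """HATS0(w) = sum (w_i h_ii)^2, with one self term per atom."""
    w, h = _validate(weights, leverages)
    terms = (w * h) ** 2
    pairs = [
        PairContribution(i=i, j=i, lag=0, value=float(v))
        for i, v in enumerate(terms, start=1)
    ]
    pairs.sort(key=lambda p: (-p.value, p.i, p.j))
    return float(terms.sum()), pairs


def hatsk(
    weights: Sequence[float],
    leverages: Sequence[float],
    topo: TopologyResult,
    k: int,
) -> tuple[float, list[PairContribution]]:
    """HATSk(w) over the pairs the Dirac delta keeps at lag k (k >= 1).

    The pair list is sorted by descending contribution, ties by (i, j), so
    coverage counts are deterministic.
    """
    w, h = _validate(weights, leverages)
    if topo.n_atoms != w.size:
        raise ValueError(f"topology is {topo.n_atoms}-atom but vectors have {w.size}")
    wh = w * h
    pairs = [
        PairContribution(i=i, j=j, lag=k, value=float(wh[i - 1] * wh[j - 1]))
        for i, j in dirac_select(topo, k)
    ]
    pairs.sort(key=lambda p: (-p.value, p.i, p.j))
    return float(sum(p.value for p in pairs)), pairs


def hats_profile(
    mol: Molecule,
    schemes: Sequence[str] = ("m",),
    lags: Iterable[int] = DEFAULT_LAGS,
    topo: TopologyResult | None = None,
    mim: MimResult | None = None,
) -> list[HatsResult]:
    """HATS(k, w) for every requested scheme and lag, with full pair lists.

    Topology and MIM are computed once and shared across schemes; pass them in
    to reuse across calls (e.g. per-conformer loops recompute the MIM only).
    """
    if not mol.bonds:
        raise ValueError(
            "molecule has no bonds; read an SDF/MOL or call perceive_bonds first"
        )
    if topo is None:
        topo = topological_distances(mol)
    if mim is None:
        mim = mim_from_molecule(mol)
    h = mim.leverages
    results = []
    for scheme in schemes:
        w = weight_vector(scheme, mol)
        values: dict[int, float] = {}
        pair_map: dict[int, tuple[PairContribution, ...]] = {}
        for k in lags:
            if k == 0:
                val, pairs = hats0(w, h)
            else:
                val, pairs = hatsk(w, h, topo, k)
            values[k] = val
            pair_map[k] = tuple(pairs)
        results.append(
            HatsResult(
                name=mol.name, scheme=scheme, values=values, pairs=pair_map, leverages=h
            )
        )
    return results


def top_pairs_coverage(
    pairs: Sequence[PairContribution], fraction: float = 0.8
) -> tuple[list[PairContribution], int, float]:
    """Smallest set of top pairs whose contributions reach a fraction of the total.

    Pairs are taken in descending-value order (ties by ascending (i, j)); the
    prefix stops as soon as its sum reaches ``fraction`` of the total value.
    Returns (subset, count, fraction actually covered).  A zero total yields an
    empty subset.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ordered = sorted(pairs, key=lambda p: (-p.value, p.i, p.j))
    total = float(sum(p.value for p in ordered))
    if total <= 0.0:
        return [], 0, 0.0
    target = fraction * total
    acc = 0.0
    subset: list[PairContribution] = []
    for p in ordered:
        subset.append(p)
        acc += p.value
        if acc >= target - _COVERAGE_RTOL * total:
            break
    return subset, len(subset), acc / total


def hats_table(results: Sequence[HatsResult], decimals: int | None = 4) -> pd.DataFrame:
    """Long-format table: one row per (molecule, scheme, lag).

    Human-readable output is rounded to 4 decimals by default; pass
    ``decimals=None`` for full precision.
    """
    rows = [
        {
            "molecule": r.name,
            "scheme": r.scheme,
            "lag": k,
            "value": round(v, decimals) if decimals is not None else v,
        }
        for r in results
        for k, v in sorted(r.values.items())
    ]
    return pd.DataFrame(rows, columns=["molecule", "scheme", "lag", "value"])
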
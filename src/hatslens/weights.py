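"""Carbon-scaled atomic weighting schemes.

HATS descriptors weight each atom by a physicochemical property divided by the
carbon value, so w(C) = 1 for every scheme.  Supported schemes follow the
Dragon/Todeschini convention:

====  ==========================================
id    property
====  ==========================================
u     unweighted (1 for every element)
m     atomic mass
v     van der Waals volume (from Bondi radii)
e     Sanderson electronegativity
p     atomic polarizability
i     first ionization potential
====  ==========================================

Raw property tables ship as a CSV resource with provenance notes
(``data/atomic_properties.csv``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import pi
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .structio import Molecule

__all__ = [
    "WeightScheme",
    "SCHEMES",
    "SCHEME_IDS",
    "atomic_weight",
    "weight_vector",
    "covalent_radius",
]


class UnsupportedElementError(KeyError):
    pass


def _load_table() -> pd.DataFrame:
    with resources.files("hatslens.data").joinpath("atomic_properties.csv").open() as fh:
        return pd.read_csv(fh, comment="#").set_index("element")


_TABLE = _load_table()


def covalent_radius(element: str) -> float:
    """Cordero single-bond covalent radius in Angstrom (for bond perception)."""
    try:
        return float(_TABLE.loc[element, "covalent_radius"])
    except KeyError:
        raise UnsupportedElementError(
            f"no covalent radius for element {element!r}"
        ) from None


@dataclass(frozen=True)
class WeightScheme:
    """One weighting scheme: raw property table plus the carbon reference."""

    id: str
    table: Mapping[str, float]
    carbon_value: float

    def weight(self, element: str) -> float:
        try:
            raw = self.table[element]
        except KeyError:
            raise UnsupportedElementError(
                f"element {element!r} not supported by scheme {self.id!r}"
            ) from None
        return raw / self.carbon_value


def _scheme_from_column(scheme_id: str, column: pd.Series) -> WeightScheme:
    table = {el: float(v) for el, v in column.items()}
    return WeightScheme(id=scheme_id, table=table, carbon_value=table["C"])


def _build_schemes() -> dict[str, WeightScheme]:
    vdw_volume = 4.0 / 3.0 * pi * _TABLE["vdw_radius"] ** 3
    unit = pd.Series(1.0, index=_TABLE.index)
    return {
        "u": _scheme_from_column("u", unit),
        "m": _scheme_from_column("m", _TABLE["mass"]),
        "v": _scheme_from_column("v", vdw_volume),
        "e": _scheme_from_column("e", _TABLE["sanderson_en"]),
        "p": _scheme_from_column("p", _TABLE["polarizability"]),
        "i": _scheme_from_column("i", _TABLE["ionization_ev"]),
    }


SCHEMES: dict[str, WeightScheme] = _build_schemes()
SCHEME_IDS: tuple[str, ...] = tuple(SCHEMES)


def _resolve(scheme: str | WeightScheme) -> WeightScheme:
    if isinstance(scheme, WeightScheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise KeyError(
            f"unknown weighting scheme {scheme!r}; available: {SCHEME_IDS}"
        ) from None


def atomic_weight(scheme: str | WeightScheme, element: str) -> float:
    """Carbon-scaled weight of one element under a scheme (w(C) = 1 exactly)."""
    return _resolve(scheme).weight(element)


def weight_vector(scheme: str | WeightScheme, mol: "Molecule") -> np.ndarray:
    """Per-atom weights in atom order (length A)."""
    ws = _resolve(scheme)
    return np.array([ws.weight(sym) for sym in mol.symbols])
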
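"""Monoenergetic coefficient tables: data model, packaged fixtures and CSV I/O.

A :class:`CoefficientTable` holds one organ's (or air kerma's) monoenergetic
dose rate coefficients versus photon energy for one exposure geometry.  The
packaged fixtures are the published fetal organ tables for the two idealized
environmental exposure conditions:

* ``ground_plane_0p5gcm2`` — uniformly contaminated infinite plane buried at
  an areal-mass depth of 0.5 g cm-2 in soil (first-year surface roughness);
  activity is per unit area, coefficients in Sv s-1 Bq-1 m2.
* ``air_submersion`` — semi-infinite uniformly contaminated air volume
  (radioactive cloud); activity per unit volume, Sv s-1 Bq-1 m3.

CSV dialect: comma-separated, ``.`` decimal, ``E`` exponent, UTF-8, one
header line ``energy_MeV,value``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _table_data as _data

__all__ = [
    "Geometry",
    "CoefficientTable",
    "MaterialSpec",
    "TableValidationError",
    "TableFormatError",
    "FixtureLookupError",
    "load_table",
    "write_table",
    "builtin_fixture",
    "available_fixtures",
    "nuclide_summary",
    "AIR",
    "SOIL",
    "E_MIN",
    "E_MAX",
]

#: Lowest / highest photon energy of the monoenergetic field calculations (MeV).
E_MIN = 0.015
E_MAX = 10.0


class TableValidationError(ValueError):
    """A coefficient table violates an invariant (ordering, sign, range)."""


class TableFormatError(ValueError):
    """A table file does not conform to the documented CSV dialect."""


class FixtureLookupError(KeyError):
    """No packaged fixture exists for the requested (geometry, organ)."""


class Geometry(enum.Enum):
    """Exposure geometry; fixes activity and coefficient units."""

    GROUND_PLANE = "ground_plane_0p5gcm2"
    AIR_SUBMERSION = "air_submersion"

    @property
    def activity_unit(self) -> str:
        return "Bq m-2" if self is Geometry.GROUND_PLANE else "Bq m-3"

    @property
    def dose_unit(self) -> str:
        return "Sv s-1 Bq-1 m2" if self is Geometry.GROUND_PLANE else "Sv s-1 Bq-1 m3"

    @property
    def kerma_unit(self) -> str:
        return "Gy s-1 Bq-1 m2" if self is Geometry.GROUND_PLANE else "Gy s-1 Bq-1 m3"


@dataclass(frozen=True)
class CoefficientTable:
    """Monoenergetic coefficients of one organ/quantity for one geometry.

    Parameters
    ----------
    geometry
        Exposure geometry; determines the coefficient units.
    organ
        Organ label (``"total_body"``, ``"skin"``, ... or ``"air_kerma"``).
    energies
        Strictly increasing photon energies in MeV, all within
        [:data:`E_MIN`, :data:`E_MAX`].
    values
        Non-negative coefficients in the geometry's units.
    quantity
        ``"equivalent_dose_rate"`` or ``"kerma_rate"``.
    """

    geometry: Geometry
    organ: str
    energies: np.ndarray
    values: np.ndarray
    quantity: str = "equivalent_dose_rate"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "values", v)
        if e.ndim != 1 or v.shape != e.shape:
            raise TableValidationError("energies and values must be matching 1-D arrays")
        if e.size < 2:
            raise TableValidationError("a coefficient table needs at least 2 nodes")
        if not np.all(np.diff(e) > 0):
            raise TableValidationError("energies must be strictly increasing")
        if e[0] < E_MIN - 1e-12 or e[-1] > E_MAX + 1e-12:
            raise TableValidationError(
                f"energies must lie within [{E_MIN}, {E_MAX}] MeV, got "
                f"[{e[0]}, {e[-1]}]"
            )
        if np.any(v < 0):
            raise TableValidationError("coefficient values must be non-negative")
        if self.quantity not in ("equivalent_dose_rate", "kerma_rate"):
            raise TableValidationError(f"unknown quantity {self.quantity!r}")

    @property
    def n_nodes(self) -> int:
        return int(self.energies.size)

    def value_at(self, energy: float) -> float:
        """Exact table value at a tabulated node (no interpolation)."""
        idx = np.nonzero(np.isclose(self.energies, energy, rtol=0, atol=1e-12))[0]
        if idx.size == 0:
            raise KeyError(f"{energy} MeV is not a tabulated node of {self.organ}")
        return float(self.values[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"energy_MeV": self.energies, "value": self.values})


@dataclass(frozen=True)
class MaterialSpec:
    """An environmental medium: density and elemental weight fractions (%)."""

    name: str
    density: float  # g cm-3
    composition: dict = field(default_factory=dict)  # element symbol -> weight %

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 100.0) > 0.1:
            raise TableValidationError(
                f"weight fractions of {self.name} sum to {total}, expected 100 +/- 0.1"
            )
        if self.density <= 0:
            raise TableValidationError("density must be positive")


#: Dry air near sea level (NIST-style composition).
AIR = MaterialSpec(
    "air", 1.2e-3, {"C": 0.01, "N": 75.53, "O": 23.18, "Ar": 1.28},
)

#: Generic mineral soil (ICRU type composition), 1 g cm-3.
SOIL = MaterialSpec(
    "soil", 1.0, {"H": 2.2, "O": 57.5, "Al": 8.5, "Si": 26.2, "Fe": 5.6},
)


def load_table(
    path,
    geometry: Geometry,
    organ: str,
    quantity: str = "equivalent_dose_rate",
) -> CoefficientTable:
    """Read a two-column ``energy_MeV,value`` CSV into a validated table.

    Raises
    ------
    TableFormatError
        Empty file or missing/renamed header columns.
    TableValidationError
        Non-monotone energies, negative values, out-of-range energies.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty table file") from exc
    missing = {"energy_MeV", "value"} - set(frame.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    if len(frame) == 0:
        raise TableFormatError(f"{path}: table has a header but no rows")
    return CoefficientTable(
        geometry=geometry,
        organ=organ,
        energies=frame["energy_MeV"].to_numpy(float),
        values=frame["value"].to_numpy(float),
        quantity=quantity,
    )


def write_table(table: CoefficientTable, path) -> None:
    """Write a table to CSV; round-trips bit-identically through load_table.

    Values are serialized with :func:`numpy.format_float_scientific`
    (``unique=True``), i.e. the shortest scientific-notation string that
    parses back to the identical double.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("energy_MeV,value\n")
        for e, v in zip(table.energies, table.values):
            es = np.format_float_scientific(e, unique=True, trim="-").upper()
            vs = np.format_float_scientific(v, unique=True, trim="-").upper()
            fh.write(f"{es},{vs}\n")


def _fixture_nodes(geometry: Geometry, organ: str):
    if organ == "air_kerma":
        rows = (
            _data.GROUND_AIR_KERMA
            if geometry is Geometry.GROUND_PLANE
            else _data.SUBMERSION_AIR_KERMA
        )
        e, v = zip(*rows)
        return np.array(e), np.array(v), "kerma_rate"
    organs = (
        _data.GROUND_ORGANS
        if geometry is Geometry.GROUND_PLANE
        else _data.SUBMERSION_ORGANS
    )
    if organ not in organs:
        raise FixtureLookupError(
            f"no packaged fixture for ({geometry.value}, {organ!r}); "
            f"available organs: {sorted(organs) + ['air_kerma']}"
        )
    energies = (
        _data.GROUND_ENERGIES
        if geometry is Geometry.GROUND_PLANE
        else _data.SUBMERSION_ENERGIES
    )
    return np.array(energies), np.array(organs[organ]), "equivalent_dose_rate"


def builtin_fixture(geometry: Geometry, organ: str) -> CoefficientTable:
    """Return a packaged table exactly as published (3 significant figures).

    ``organ`` may be any fetal organ label of the published tables or
    ``"air_kerma"`` for the kerma rate at 1 m above ground.
    """
    e, v, quantity = _fixture_nodes(geometry, organ)
    return CoefficientTable(geometry, organ, e, v, quantity)


def available_fixtures() -> dict:
    """Mapping geometry -> tuple of packaged organ labels."""
    return {
        Geometry.GROUND_PLANE: tuple(sorted(_data.GROUND_ORGANS)) + ("air_kerma",),
        Geometry.AIR_SUBMERSION: tuple(sorted(_data.SUBMERSION_ORGANS)) + ("air_kerma",),
    }


def nuclide_summary(geometry: Geometry) -> pd.DataFrame:
    """Packaged per-nuclide summary coefficients (curated published subset).

    Columns: ``air_kerma`` (Gy s-1 per unit activity concentration),
    ``detriment_weighted`` and ``uterus`` of the pregnant mother, and fetal
    ``total_body`` (Sv s-1 per unit activity concentration); progeny excluded.
    """
    idx = 0 if geometry is Geometry.GROUND_PLANE else 1
    rows = {
        nuc: vals[idx] for nuc, vals in _data.NUCLIDE_SUMMARY.items()
    }
    frame = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["air_kerma", "detriment_weighted", "uterus", "total_body"],
    )
    frame.index.name = "nuclide"
    return frame
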
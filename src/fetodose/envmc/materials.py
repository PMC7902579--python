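"""Photon interaction data for the environmental media.

No cross-section library is bundled.  The packaged interaction data are
*synthetic*: the incoherent part is the analytic free-electron Klein-Nishina
cross-section scaled by the mixture's electron density, and the
photoelectric and pair parts are simple power-law models calibrated to a few
standard dry-air anchor values.  This is adequate for the simplified analog
engine (whose acceptance properties are closed-form self-consistency checks)
and is replaceable by user CSV tables with measured coefficients.

The fluence-to-kerma conversion uses a typed table of standard dry-air mass
energy-absorption coefficients (the radiative-loss difference between the
energy-transfer and energy-absorption coefficient is negligible in air below
a few MeV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..dose_tables import MaterialSpec, AIR

__all__ = [
    "AttenuationTable",
    "make_attenuation_table",
    "air_mu_tr_table",
    "klein_nishina_total",
    "MissingAttenuationError",
]

_ELECTRON_REST_MEV = 0.511
_R_E_CM = 2.8179403262e-13  # classical electron radius
_N_A = 6.02214076e23

# element symbol -> (Z, A)
_ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Al": (13, 26.982), "Si": (14, 28.085), "Ar": (18, 39.948),
    "Fe": (26, 55.845),
}

_PAIR_THRESHOLD = 2.0 * _ELECTRON_REST_MEV


class MissingAttenuationError(ValueError):
    """Requested energy outside the attenuation table's grid."""


def klein_nishina_total(energy_mev) -> np.ndarray:
    """Total Klein-Nishina cross-section per free electron (cm^2)."""
    a = np.asarray(energy_mev, float) / _ELECTRON_REST_MEV
    term1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    term2 = np.log1p(2 * a) / (2 * a)
    term3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2.0 * np.pi * _R_E_CM**2 * (term1 + term2 - term3)


def _mixture_sums(material: MaterialSpec):
    z_over_a = pe = z2_over_a = 0.0
    for sym, pct in material.composition.items():
        z, a = _ELEMENTS[sym]
        w = pct / 100.0
        z_over_a += w * z / a
        pe += w * z**4.3 / a
        z2_over_a += w * z**2 / a
    return z_over_a, pe, z2_over_a


# Photoelectric model tau/rho = A_PE * sum_i w_i Z_i^4.3/A_i * E^-3.1,
# calibrated so dry air gives ~4.5 cm^2/g at 0.01 MeV.
_AIR_PE_SUM = _mixture_sums(AIR)[1]
_A_PE = 4.5 / (_AIR_PE_SUM * 0.01**-3.1)

# Pair model kappa/rho = A_PP * sum_i w_i Z_i^2/A_i * (E-1.022)^1.5/sqrt(E),
# calibrated so dry air gives ~3.9e-4 cm^2/g at 2 MeV.
_AIR_Z2_SUM = _mixture_sums(AIR)[2]
_A_PP = 3.9e-4 / (_AIR_Z2_SUM * (2.0 - _PAIR_THRESHOLD) ** 1.5 / np.sqrt(2.0))


@dataclass(frozen=True)
class AttenuationTable:
    """Partial mass attenuation coefficients of one medium on an energy grid.

    Columns are photoelectric, incoherent (Compton) and pair coefficients in
    cm^2/g; interpolation is log-log per partial within its support.
    Energies outside the grid raise :class:`MissingAttenuationError`.
    """

    material: MaterialSpec
    energies: np.ndarray  # MeV, strictly increasing
    photoelectric: np.ndarray
    incoherent: np.ndarray
    pair: np.ndarray

    def __post_init__(self) -> None:
        for name in ("energies", "photoelectric", "incoherent", "pair"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not np.all(np.diff(self.energies) > 0):
            raise ValueError("attenuation energies must be strictly increasing")
        for arr in (self.photoelectric, self.incoherent, self.pair):
            if arr.shape != self.energies.shape or np.any(arr < 0):
                raise ValueError("partial coefficients must be non-negative, matching grid")

    def _check_range(self, e: np.ndarray) -> None:
        if np.any(e < self.energies[0] * (1 - 1e-9)) or np.any(
            e > self.energies[-1] * (1 + 1e-9)
        ):
            raise MissingAttenuationError(
                f"energy outside attenuation grid "
                f"[{self.energies[0]}, {self.energies[-1]}] MeV for "
                f"{self.material.name}"
            )

    def _loglog(self, e: np.ndarray, partial: np.ndarray) -> np.ndarray:
        mask = partial > 0
        if mask.sum() < 2:
            return np.zeros_like(e)
        xs, ys = np.log(self.energies[mask]), np.log(partial[mask])
        out = np.exp(np.interp(np.log(e), xs, ys))
        # outside the partial's own support the coefficient is zero
        out[(e < self.energies[mask][0]) | (e > self.energies[mask][-1])] = 0.0
        return out

    def partials(self, energy_mev):
        """(photoelectric, incoherent, pair) mass coefficients at E (cm^2/g)."""
        e = np.atleast_1d(np.asarray(energy_mev, float))
        self._check_range(e)
        return (
            self._loglog(e, self.photoelectric),
            self._loglog(e, self.incoherent),
            self._loglog(e, self.pair),
        )

    def mu_total(self, energy_mev) -> np.ndarray:
        """Total linear attenuation coefficient at E (1/m)."""
        pe, inc, pp = self.partials(energy_mev)
        return (pe + inc + pp) * self.material.density * 100.0  # cm2/g * g/cm3 -> 1/cm -> 1/m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "energy_MeV": self.energies,
                "photoelectric": self.photoelectric,
                "incoherent": self.incoherent,
                "pair": self.pair,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, material: MaterialSpec) -> "AttenuationTable":
        frame = pd.read_csv(path)
        missing = {"energy_MeV", "photoelectric", "incoherent", "pair"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing attenuation columns {sorted(missing)}")
        return cls(
            material,
            frame["energy_MeV"].to_numpy(float),
            frame["photoelectric"].to_numpy(float),
            frame["incoherent"].to_numpy(float),
            frame["pair"].to_numpy(float),
        )


def make_attenuation_table(
    material: MaterialSpec,
    e_min: float = 0.002,
    e_max: float = 10.0,
    n: int = 160,
) -> AttenuationTable:
    """Build the synthetic attenuation table for a medium (see module docs)."""
    e = np.geomspace(e_min, e_max, n)
    z_over_a, pe_sum, z2_sum = _mixture_sums(material)
    incoherent = klein_nishina_total(e) * _N_A * z_over_a
    photoelectric = _A_PE * pe_sum * e**-3.1
    pair = np.where(
        e > _PAIR_THRESHOLD,
        _A_PP * z2_sum * np.maximum(e - _PAIR_THRESHOLD, 0.0) ** 1.5 / np.sqrt(e),
        0.0,
    )
    return AttenuationTable(material, e, photoelectric, incoherent, pair)


# Standard dry-air mass energy-absorption coefficients (cm^2/g); used as the
# fluence-to-kerma conversion mu_tr/rho (radiative losses in air are
# negligible over this range).
_AIR_MU_TR = (
    (0.010, 4.742), (0.015, 1.334), (0.020, 0.5389), (0.030, 0.1537),
    (0.040, 0.06833), (0.050, 0.04098), (0.060, 0.03041), (0.080, 0.02407),
    (0.100, 0.02325), (0.150, 0.02496), (0.200, 0.02672), (0.300, 0.02872),
    (0.400, 0.02949), (0.500, 0.02966), (0.600, 0.02953), (0.800, 0.02882),
    (1.000, 0.02789), (1.250, 0.02666), (1.500, 0.02547), (2.000, 0.02345),
    (3.000, 0.02057), (4.000, 0.01870), (5.000, 0.01740), (6.000, 0.01647),
    (8.000, 0.01525), (10.000, 0.01450),
)


def air_mu_tr_table() -> pd.DataFrame:
    """(E, mu_tr/rho) pairs for dry air, cm^2/g, 0.01-10 MeV."""
    return pd.DataFrame(_AIR_MU_TR, columns=["energy_MeV", "mu_tr_over_rho"])
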
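"""Radionuclide decay records, bremsstrahlung kernels and weighting factors.

Decay data are carried in a small documented JSON schema holding the same
content as a nuclear decay-data compilation record: discrete photon and
electron lines with per-decay yields, and continuous spectra (beta electrons,
spontaneous-fission photons) as tabulated yield densities.  Native
decay-database file formats are deliberately not parsed; a converter into
this schema is left to the user, which keeps the package download-free.

JSON schema (one object per nuclide)::

    {
      "nuclide": "Cs-137",
      "discrete": [
        {"type": "photon" | "electron", "energy_MeV": 0.6617, "yield": 0.851},
        ...
      ],
      "continuous": [
        {"type": "electron_beta" | "photon_sf",
         "grid": [[E_MeV, dY/dE per MeV], ...]},   # E strictly increasing
        ...
      ]
    }

Electrons (discrete lines and beta continua alike) contribute to
environmental dose only through the bremsstrahlung photons they generate
while stopping in soil or air; a :class:`BremsKernel` carries the
thick-target photon spectrum per monoenergetic stopping electron.  The
default kernel built by :func:`kramers_kernel` is a truncated 1/k
(Kramers-like) shape scaled to a user-supplied radiative yield; a measured
kernel can be loaded from CSV instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .dose_tables import MaterialSpec

__all__ = [
    "DiscreteEmission",
    "ContinuousSpectrum",
    "DecayRecord",
    "BremsKernel",
    "WeightingConfig",
    "DecayDataError",
    "parse_decay_json",
    "serialize_decay_json",
    "synth_nuclide",
    "SynthSpec",
    "kramers_kernel",
    "load_kernel_csv",
    "ICRP103_TISSUE_WEIGHTS",
]

_ELECTRON_REST_MEV = 0.511


class DecayDataError(ValueError):
    """Decay record or kernel violates the schema or an invariant."""


@dataclass(frozen=True)
class DiscreteEmission:
    """One discrete line: radiation type, energy (MeV), per-decay yield."""

    radiation_type: str  # "photon" | "electron"
    energy: float
    yield_: float

    def __post_init__(self) -> None:
        if self.radiation_type not in ("photon", "electron"):
            raise DecayDataError(f"unknown radiation type {self.radiation_type!r}")
        if not self.energy > 0:
            raise DecayDataError(f"line energy must be positive, got {self.energy}")
        if self.yield_ < 0:
            raise DecayDataError(f"yield must be non-negative, got {self.yield_}")


@dataclass(frozen=True)
class ContinuousSpectrum:
    """Tabulated per-decay yield density dY/dE (MeV-1) on an energy grid."""

    radiation_type: str  # "electron_beta" | "photon_sf"
    grid: np.ndarray  # shape (n, 2): (E_MeV, density)

    def __post_init__(self) -> None:
        if self.radiation_type not in ("electron_beta", "photon_sf"):
            raise DecayDataError(f"unknown spectrum type {self.radiation_type!r}")
        g = np.asarray(self.grid, float)
        object.__setattr__(self, "grid", g)
        if g.ndim != 2 or g.shape[1] != 2 or g.shape[0] < 2:
            raise DecayDataError("spectrum grid must be an (n>=2, 2) array")
        if not np.all(np.diff(g[:, 0]) > 0):
            raise DecayDataError("spectrum energies must be strictly increasing")
        if np.any(g[:, 0] <= 0):
            raise DecayDataError("spectrum energies must be positive")
        if np.any(g[:, 1] < 0):
            raise DecayDataError("spectrum densities must be non-negative")

    @property
    def energies(self) -> np.ndarray:
        return self.grid[:, 0]

    @property
    def densities(self) -> np.ndarray:
        return self.grid[:, 1]

    def total_yield(self) -> float:
        """Integral of the density over the grid (particles per decay)."""
        return float(np.trapezoid(self.densities, self.energies))


@dataclass(frozen=True)
class DecayRecord:
    """One nuclide's emissions per nuclear transformation (progeny excluded)."""

    nuclide: str
    discrete: tuple = ()
    continuous: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "discrete", tuple(self.discrete))
        object.__setattr__(self, "continuous", tuple(self.continuous))

    def lines(self, radiation_type: str) -> tuple:
        return tuple(d for d in self.discrete if d.radiation_type == radiation_type)

    def spectra(self, radiation_type: str) -> tuple:
        return tuple(c for c in self.continuous if c.radiation_type == radiation_type)

    def scaled(self, factor: float) -> "DecayRecord":
        """Record with every yield multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise DecayDataError("scale factor must be non-negative")
        return DecayRecord(
            self.nuclide,
            tuple(
                DiscreteEmission(d.radiation_type, d.energy, d.yield_ * factor)
                for d in self.discrete
            ),
            tuple(
                ContinuousSpectrum(
                    c.radiation_type,
                    np.column_stack([c.energies, c.densities * factor]),
                )
                for c in self.continuous
            ),
        )


def parse_decay_json(source) -> DecayRecord:
    """Parse a decay record from a path, file object or JSON string.

    Errors carry the JSON path of the offending field.
    """
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        text = None
        s = str(source)
        if s.lstrip().startswith("{"):
            text = s
        else:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        payload = json.loads(text)
    if not isinstance(payload, dict):
        raise DecayDataError("$: decay record must be a JSON object")
    if "nuclide" not in payload or not isinstance(payload["nuclide"], str):
        raise DecayDataError("$.nuclide: missing or not a string")
    discrete = []
    for i, item in enumerate(payload.get("discrete", [])):
        where = f"$.discrete[{i}]"
        if not isinstance(item, dict):
            raise DecayDataError(f"{where}: must be an object")
        try:
            discrete.append(
                DiscreteEmission(
                    item.get("type", "photon"),
                    float(item["energy_MeV"]),
                    float(item["yield"]),
                )
            )
        except KeyError as exc:
            raise DecayDataError(f"{where}.{exc.args[0]}: missing field") from exc
        except DecayDataError as exc:
            raise DecayDataError(f"{where}: {exc}") from exc
    continuous = []
    for i, item in enumerate(payload.get("continuous", [])):
        where = f"$.continuous[{i}]"
        if not isinstance(item, dict) or "grid" not in item:
            raise DecayDataError(f"{where}.grid: missing field")
        try:
            continuous.append(
                ContinuousSpectrum(
                    item.get("type", "electron_beta"), np.asarray(item["grid"], float)
                )
            )
        except DecayDataError as exc:
            raise DecayDataError(f"{where}: {exc}") from exc
    return DecayRecord(payload["nuclide"], tuple(discrete), tuple(continuous))


def serialize_decay_json(record: DecayRecord) -> str:
    """Inverse of :func:`parse_decay_json` (semantically lossless)."""
    payload = {
        "nuclide": record.nuclide,
        "discrete": [
            {"type": d.radiation_type, "energy_MeV": d.energy, "yield": d.yield_}
            for d in record.discrete
        ],
        "continuous": [
            {"type": c.radiation_type, "grid": c.grid.tolist()}
            for c in record.continuous
        ],
    }
    return json.dumps(payload, indent=1)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic nuclide generator.

    ``n_lines`` discrete photon lines uniform in log-energy on
    ``energy_range``; ``n_beta`` allowed-shape beta branches with endpoints
    uniform on ``beta_endpoint_range``; per-line/per-branch yields uniform on
    ``yield_range``.  All energies in MeV, within (0, 10].
    """

    n_lines: int = 3
    energy_range: tuple = (0.03, 3.0)
    n_beta: int = 1
    beta_endpoint_range: tuple = (0.1, 2.5)
    yield_range: tuple = (0.05, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.energy_range, self.beta_endpoint_range):
            if not (0 < lo <= hi <= 10.0):
                raise DecayDataError("spec ranges must lie within (0, 10] MeV")
        if self.n_lines < 0 or self.n_beta < 0:
            raise DecayDataError("counts must be non-negative")
        if self.n_lines == 0 and self.n_beta == 0:
            raise DecayDataError("empty spec: need at least one line or beta branch")


def _allowed_beta_shape(e: np.ndarray, endpoint: float) -> np.ndarray:
    """Allowed-transition beta shape p*W*(Q-T)^2 (Fermi function omitted)."""
    w = e + _ELECTRON_REST_MEV
    p = np.sqrt(np.maximum(e * (e + 2.0 * _ELECTRON_REST_MEV), 0.0))
    return p * w * np.maximum(endpoint - e, 0.0) ** 2


def synth_nuclide(seed: int, spec: SynthSpec = SynthSpec()) -> DecayRecord:
    """Generate a reproducible synthetic decay record for tests and demos.

    The same ``seed`` always yields the identical record.
    """
    rng = np.random.default_rng(seed)
    lines = []
    lo, hi = spec.energy_range
    for _ in range(spec.n_lines):
        e = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        y = float(rng.uniform(*spec.yield_range))
        lines.append(DiscreteEmission("photon", e, y))
    spectra = []
    for _ in range(spec.n_beta):
        q = float(rng.uniform(*spec.beta_endpoint_range))
        y = float(rng.uniform(*spec.yield_range))
        e = np.linspace(q * 1e-3, q, 64)
        shape = _allowed_beta_shape(e, q)
        norm = np.trapezoid(shape, e)
        spectra.append(
            ContinuousSpectrum(
                "electron_beta", np.column_stack([e, y * shape / norm])
            )
        )
    return DecayRecord(f"Synth-{seed}", tuple(lines), tuple(spectra))


@dataclass(frozen=True)
class BremsKernel:
    """Thick-target bremsstrahlung photon spectra per stopping electron.

    For each initial electron energy ``E_e`` on ``electron_energies`` the
    kernel tabulates ``B(k | E_e)`` (photons MeV-1 per stopping electron) on
    a photon-energy grid with support k <= E_e.  The radiated-energy bound
    ``integral k B dk <= E_e`` is enforced on construction.
    """

    medium: str
    electron_energies: np.ndarray
    photon_grids: tuple  # one strictly increasing k grid per electron energy
    spectra: tuple  # matching B arrays

    def __post_init__(self) -> None:
        ee = np.asarray(self.electron_energies, float)
        object.__setattr__(self, "electron_energies", ee)
        if ee.size < 1 or not np.all(np.diff(ee) > 0):
            raise DecayDataError("electron grid must be strictly increasing, size >= 1")
        if len(self.photon_grids) != ee.size or len(self.spectra) != ee.size:
            raise DecayDataError("one photon grid and spectrum per electron energy")
        grids = tuple(np.asarray(g, float) for g in self.photon_grids)
        specs = tuple(np.asarray(b, float) for b in self.spectra)
        object.__setattr__(self, "photon_grids", grids)
        object.__setattr__(self, "spectra", specs)
        for e_e, k, b in zip(ee, grids, specs):
            if k.shape != b.shape or k.ndim != 1:
                raise DecayDataError("photon grid / spectrum shape mismatch")
            if np.any(np.diff(k) <= 0) or np.any(k <= 0):
                raise DecayDataError("photon grids must be positive, increasing")
            if np.any(b < 0):
                raise DecayDataError("bremsstrahlung spectra must be non-negative")
            if k[-1] > e_e * (1 + 1e-12):
                raise DecayDataError("kernel support must satisfy k <= E_e")
            radiated = np.trapezoid(k * b, k)
            if radiated > e_e * (1 + 1e-9):
                raise DecayDataError(
                    f"radiated energy {radiated} MeV exceeds electron energy {e_e}"
                )

    def radiated_energy(self, index: int) -> float:
        """Trapezoid integral of k*B over the stored grid (MeV)."""
        k, b = self.photon_grids[index], self.spectra[index]
        return float(np.trapezoid(k * b, k))

    def spectrum_at(self, e_electron: float):
        """(k grid, B) at ``e_electron``, linearly interpolated in E_e.

        Spectra at the two bracketing tabulated electron energies are
        combined on the query's own support (0, e_electron].
        """
        ee = self.electron_energies
        if e_electron < ee[0] * (1 - 1e-12) or e_electron > ee[-1] * (1 + 1e-12):
            raise DecayDataError(
                f"electron energy {e_electron} MeV outside kernel grid "
                f"[{ee[0]}, {ee[-1]}]"
            )
        j = int(np.clip(np.searchsorted(ee, e_electron) - 1, 0, ee.size - 2)) \
            if ee.size > 1 else 0
        if ee.size == 1:
            return self.photon_grids[0], self.spectra[0]
        t = (e_electron - ee[j]) / (ee[j + 1] - ee[j])
        t = float(np.clip(t, 0.0, 1.0))
        k = np.unique(np.concatenate([
            self.photon_grids[j][self.photon_grids[j] <= e_electron],
            self.photon_grids[j + 1][self.photon_grids[j + 1] <= e_electron],
            [e_electron],
        ]))
        b_lo = np.interp(k, self.photon_grids[j], self.spectra[j], left=0.0, right=0.0)
        b_hi = np.interp(
            k, self.photon_grids[j + 1], self.spectra[j + 1], left=0.0, right=0.0
        )
        return k, (1.0 - t) * b_lo + t * b_hi


def kramers_kernel(
    medium: MaterialSpec,
    radiative_yield_table,
    k_min: float = 1e-3,
    n_k: int = 80,
) -> BremsKernel:
    """Default bremsstrahlung kernel: truncated 1/k shape, yield-scaled.

    ``radiative_yield_table`` is a sequence of ``(E_e_MeV, Y_rad)`` pairs
    with radiative yields in [0, 1].  For each electron energy the spectrum
    is ``B(k | E_e) = c / k`` on [k_min, E_e], with ``c`` chosen so that the
    radiated energy equals ``Y_rad(E_e) * E_e``:

        integral_0^Ee k (c/k) dk = c E_e  =>  c = Y_rad(E_e).

    This is an approximation standing in for a measured thick-target
    kernel, which can be supplied via :func:`load_kernel_csv` instead.
    """
    pairs = sorted((float(e), float(y)) for e, y in radiative_yield_table)
    if not pairs:
        raise DecayDataError("radiative yield table must not be empty")
    ee, yy = zip(*pairs)
    if any(y < 0 or y > 1 for y in yy):
        raise DecayDataError("radiative yields must lie in [0, 1]")
    grids, specs = [], []
    for e_e, y in pairs:
        k_lo = min(k_min, e_e / 10.0)
        k = np.geomspace(k_lo, e_e, n_k)
        grids.append(k)
        # scale on the truncated support so the radiated energy equals
        # Y_rad * E_e exactly (k*B is constant, so the trapezoid is exact)
        specs.append(y * e_e / (e_e - k_lo) / k)
    return BremsKernel(medium.name, np.asarray(ee), tuple(grids), tuple(specs))


def load_kernel_csv(path, medium: str = "user") -> BremsKernel:
    """Load a kernel from CSV with columns ``E_e_MeV,k_MeV,B``."""
    import pandas as pd

    frame = pd.read_csv(path)
    missing = {"E_e_MeV", "k_MeV", "B"} - set(frame.columns)
    if missing:
        raise DecayDataError(f"{path}: missing kernel columns {sorted(missing)}")
    ee, grids, specs = [], [], []
    for e_e, group in frame.groupby("E_e_MeV", sort=True):
        g = group.sort_values("k_MeV")
        ee.append(float(e_e))
        grids.append(g["k_MeV"].to_numpy(float))
        specs.append(g["B"].to_numpy(float))
    return BremsKernel(medium, np.asarray(ee), tuple(grids), tuple(specs))


#: Tissue weighting factors of the current radiological-protection system
#: (gonads 0.08; bone marrow, colon, lung, stomach, breast and the pooled
#: remainder 0.12 each; bladder, oesophagus, liver, thyroid 0.04 each; bone
#: surface, brain, salivary glands, skin 0.01 each).  Sums to 1.
ICRP103_TISSUE_WEIGHTS = {
    "gonads": 0.08,
    "red_bone_marrow": 0.12,
    "colon": 0.12,
    "lungs": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "remainder": 0.12,
    "bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surface": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01,
}


@dataclass(frozen=True)
class WeightingConfig:
    """Radiation and tissue weights entering the folding sum.

    Photons and electrons both carry radiation weight 1 by default (the
    low-LET value).  ``tissue_weights`` is only needed for the
    detriment-weighted scalar; when a full set is supplied it must sum to 1.
    """

    radiation_weights: dict = field(
        default_factory=lambda: {"photon": 1.0, "electron": 1.0}
    )
    tissue_weights: dict = field(default_factory=dict)
    full_tissue_set: bool = False

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.radiation_weights.values()):
            raise DecayDataError("radiation weights must be non-negative")
        if self.full_tissue_set and self.tissue_weights:
            total = sum(self.tissue_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise DecayDataError(
                    f"full tissue weight set must sum to 1, got {total}"
                )

    def w_r(self, radiation_type: str) -> float:
        base = radiation_type.split("_")[0]  # electron_beta -> electron
        if base == "photon" or radiation_type == "photon_sf":
            base = "photon"
        return float(self.radiation_weights.get(base, 1.0))
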
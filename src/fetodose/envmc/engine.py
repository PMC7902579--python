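"""Analog photon transport in the air-over-soil cylinder world.

Geometry: a right circular cylinder of radius ``world_radius_m`` holding an
air layer (0 <= z <= ``air_height_m``) over a soil layer
(-``soil_thickness_m`` <= z < 0).  Sources are either the buried
contamination plane (z = -depth, with the 0.5 g cm-2 areal-mass depth
converted to length through the soil density) or a uniform air volume up to
``source_height_m`` (clamped to the air layer).  An optional coupling
cylinder standing on the ground is an ideal absorber: any photon entering it
is terminated and its crossing recorded (energy, direction cosine against
the upward vertical, emission height for side crossings).

Physics per interaction: photoelectric absorption, free-electron
Klein-Nishina Compton scattering, and pair production terminating the photon
while emitting two isotropic 0.511 MeV annihilation quanta.  Secondary
electrons are not followed.  Photons below the energy cutoff are terminated
on the spot.  All histories are analog (weight 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..dose_tables import AIR, SOIL, MaterialSpec
from .materials import AttenuationTable, make_attenuation_table
from .kinematics import sample_klein_nishina, rotate_directions

__all__ = [
    "FieldConfig",
    "CouplingCylinder",
    "FieldResult",
    "run_field",
    "transport_photon",
    "PhotonEvent",
]

_ANNIHILATION_MEV = 0.511
_EPS = 1e-9  # boundary nudge, meters

SIDE, TOP_LID, BOTTOM_LID = 1, 2, 3
_SURFACE_NAMES = {SIDE: "side", TOP_LID: "lid", BOTTOM_LID: "lid_bottom"}


@dataclass(frozen=True)
class FieldConfig:
    """World, media, source and run parameters of an environmental field run."""

    energy_MeV: float
    histories: int
    seed: int = 0
    source: str = "ground_plane"  # "ground_plane" | "air_volume"
    source_depth_gcm2: float = 0.5
    source_height_m: float = 1000.0
    world_radius_m: float = 500.0
    air_height_m: float = 500.0
    soil_thickness_m: float = 1.0
    cutoff_MeV: float = 0.002
    air: MaterialSpec = field(default_factory=lambda: AIR)
    soil: MaterialSpec = field(default_factory=lambda: SOIL)

    def __post_init__(self) -> None:
        if self.histories < 1:
            raise ValueError("histories must be >= 1")
        if not 0 < self.cutoff_MeV < self.energy_MeV:
            raise ValueError("cutoff must satisfy 0 < cutoff < source energy")
        if self.source not in ("ground_plane", "air_volume"):
            raise ValueError(f"unknown source kind {self.source!r}")
        if self.source_depth_m >= self.soil_thickness_m:
            raise ValueError("plane source depth exceeds the soil layer")

    @property
    def source_depth_m(self) -> float:
        """Areal-mass depth g cm-2 -> meters through the soil density."""
        return self.source_depth_gcm2 / self.soil.density / 100.0

    @property
    def effective_source_height_m(self) -> float:
        return min(self.source_height_m, self.air_height_m)


@dataclass(frozen=True)
class CouplingCylinder:
    """Ideal-absorber virtual cylinder, base on the ground, axis vertical."""

    radius_m: float
    height_m: float

    def __post_init__(self) -> None:
        if self.radius_m <= 0 or self.height_m <= 0:
            raise ValueError("cylinder dimensions must be positive")

    @classmethod
    def ground(cls) -> "CouplingCylinder":
        """Ground-contamination default: 2 m diameter, 2.5 m height."""
        return cls(1.0, 2.5)

    @classmethod
    def submersion(cls) -> "CouplingCylinder":
        """Air-submersion default: 0.6 m diameter, 2 m height."""
        return cls(0.3, 2.0)


@dataclass
class FieldResult:
    """Raw crossing log (one row per coupling-cylinder entry) plus run info."""

    config: FieldConfig
    cylinder: CouplingCylinder | None
    crossings: pd.DataFrame
    n_histories: int

    def pdf(self, cutoff: float | None = None):
        """Binned phase-space densities of the recorded crossings."""
        from .phase_space import bin_phase_space

        return bin_phase_space(
            self.crossings,
            self.cylinder,
            self.config.energy_MeV,
            cutoff if cutoff is not None else self.config.cutoff_MeV,
        )

    def write_crossings(self, path) -> None:
        self.crossings.to_csv(path, index=False)


def default_attenuation(config: FieldConfig) -> dict:
    """Synthetic attenuation tables for the configured air and soil."""
    lo = min(config.cutoff_MeV, 0.002)
    return {
        "air": make_attenuation_table(config.air, e_min=lo),
        "soil": make_attenuation_table(config.soil, e_min=lo),
    }


def _sample_source(config: FieldConfig, rng: np.random.Generator, n: int):
    r = config.world_radius_m * np.sqrt(rng.random(n))
    phi = rng.uniform(0, 2 * np.pi, n)
    x, y = r * np.cos(phi), r * np.sin(phi)
    if config.source == "ground_plane":
        z = np.full(n, -config.source_depth_m)
    else:
        z = rng.uniform(0.0, config.effective_source_height_m, n)
    pos = np.column_stack([x, y, z])
    dirs = _isotropic(rng, n)
    e = np.full(n, config.energy_MeV)
    return pos, dirs, e


def _isotropic(rng: np.random.Generator, n: int) -> np.ndarray:
    w = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - w**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), w])


def _world_exit_distance(pos, dirs, config: FieldConfig) -> np.ndarray:
    x, y, z = pos.T
    u, v, w = dirs.T
    inf = np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        t_top = np.where(w > 0, (config.air_height_m - z) / w, inf)
        t_bot = np.where(w < 0, (-config.soil_thickness_m - z) / w, inf)
    a = u**2 + v**2
    b = 2.0 * (x * u + y * v)
    c = x**2 + y**2 - config.world_radius_m**2
    disc = np.maximum(b**2 - 4 * a * c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_side = np.where(a > 0, (-b + np.sqrt(disc)) / (2 * a), inf)
    t_side = np.where(t_side > 0, t_side, inf)
    return np.minimum(np.minimum(t_top, t_bot), t_side)


def _interface_distance(pos, dirs) -> np.ndarray:
    z = pos[:, 2]
    w = dirs[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -z / w
    toward = ((z > 0) & (w < 0)) | ((z < 0) & (w > 0))
    return np.where(toward & (t > 0), t, np.inf)


def _cylinder_entry(pos, dirs, cyl: CouplingCylinder):
    """(distance, surface code) of entry into the coupling cylinder, inf if none."""
    x, y, z = pos.T
    u, v, w = dirs.T
    n = x.size
    t_best = np.full(n, np.inf)
    code = np.zeros(n, dtype=np.int8)

    a = u**2 + v**2
    b = 2.0 * (x * u + y * v)
    c = x**2 + y**2 - cyl.radius_m**2
    disc = b**2 - 4 * a * c
    with np.errstate(divide="ignore", invalid="ignore"):
        t_side = (-b - np.sqrt(np.maximum(disc, 0.0))) / (2 * a)
    z_hit = z + w * t_side
    ok_side = (a > 0) & (disc > 0) & (c > 0) & (t_side > _EPS)
    ok_side &= (z_hit >= 0.0) & (z_hit <= cyl.height_m)
    t_best = np.where(ok_side, t_side, t_best)
    code = np.where(ok_side, SIDE, code)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_top = (cyl.height_m - z) / w
    r2_top = (x + u * t_top) ** 2 + (y + v * t_top) ** 2
    ok_top = (z > cyl.height_m) & (w < 0) & (t_top > _EPS)
    ok_top &= r2_top <= cyl.radius_m**2
    better = ok_top & (t_top < t_best)
    t_best = np.where(better, t_top, t_best)
    code = np.where(better, TOP_LID, code)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_bot = -z / w
    r2_bot = (x + u * t_bot) ** 2 + (y + v * t_bot) ** 2
    ok_bot = (z < 0.0) & (w > 0) & (t_bot > _EPS) & (r2_bot <= cyl.radius_m**2)
    better = ok_bot & (t_bot < t_best)
    t_best = np.where(better, t_bot, t_best)
    code = np.where(better, BOTTOM_LID, code)
    return t_best, code


def _mu_total(attenuation, in_air, energy) -> np.ndarray:
    """Total linear attenuation (1/m) per photon given its medium."""
    mu = np.zeros(energy.size)
    for medium, mask in (("air", in_air), ("soil", ~in_air)):
        table = attenuation.get(medium)
        if table is not None and np.any(mask):
            mu[mask] = table.mu_total(energy[mask])
    return mu


def _interact(attenuation, in_air, pos, dirs, energy, cutoff, rng):
    """Sample interaction types; return survivors and annihilation secondaries."""
    n = energy.size
    p_pe = np.zeros(n)
    p_inc = np.zeros(n)
    p_pp = np.zeros(n)
    for medium, mask in (("air", in_air), ("soil", ~in_air)):
        table = attenuation.get(medium)
        if table is not None and np.any(mask):
            pe, inc, pp = table.partials(energy[mask])
            tot = pe + inc + pp
            tot[tot == 0] = 1.0
            p_pe[mask], p_inc[mask], p_pp[mask] = pe / tot, inc / tot, pp / tot
    xi = rng.random(n)
    is_compton = (xi >= p_pe) & (xi < p_pe + p_inc)
    is_pair = xi >= p_pe + p_inc

    sec_pos = pos[is_pair]
    if sec_pos.size:
        sec_pos = np.repeat(sec_pos, 2, axis=0)
        sec_dirs = _isotropic(rng, sec_pos.shape[0])
        sec_e = np.full(sec_pos.shape[0], _ANNIHILATION_MEV)
    else:
        sec_pos = np.empty((0, 3))
        sec_dirs = np.empty((0, 3))
        sec_e = np.empty(0)

    out_pos = pos[is_compton]
    out_dirs = dirs[is_compton]
    out_e = energy[is_compton]
    if out_e.size:
        cos_t, e_new = sample_klein_nishina(rng, out_e)
        out_dirs = rotate_directions(rng, out_dirs, cos_t)
        keep = e_new >= cutoff  # below-cutoff photons terminated on the spot
        out_pos, out_dirs, out_e = out_pos[keep], out_dirs[keep], e_new[keep]
    return (out_pos, out_dirs, out_e), (sec_pos, sec_dirs, sec_e)


def _transport_batch(
    config: FieldConfig,
    attenuation: dict,
    cylinder: CouplingCylinder | None,
    pos, dirs, energy,
    rng: np.random.Generator,
    record: list | None,
    scorer=None,
    batch_index: int = 0,
) -> None:
    tau = rng.exponential(size=energy.size)
    while energy.size:
        in_air = pos[:, 2] >= 0.0
        mu = _mu_total(attenuation, in_air, energy)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_free = np.where(mu > 0, tau / np.where(mu > 0, mu, 1.0), np.inf)
        d_world = _world_exit_distance(pos, dirs, config)
        d_iface = _interface_distance(pos, dirs)
        if cylinder is not None:
            d_cyl, cyl_code = _cylinder_entry(pos, dirs, cylinder)
        else:
            d_cyl = np.full(energy.size, np.inf)
            cyl_code = np.zeros(energy.size, dtype=np.int8)
        d_geom = np.minimum(np.minimum(d_world, d_iface), d_cyl)
        step = np.minimum(d_free, d_geom)
        # a photon numerically outside every boundary sees no finite distance;
        # treat it as escaped (zero step, classified into no category below)
        finite = np.isfinite(step)
        step = np.where(finite, step, 0.0)

        if scorer is not None:
            z0 = pos[:, 2]
            z1 = z0 + dirs[:, 2] * step
            seg_air = in_air  # legs never straddle the interface
            if np.any(seg_air):
                scorer.score(
                    energy[seg_air], z0[seg_air], z1[seg_air], step[seg_air],
                    batch_index,
                )

        interacted = finite & (d_free < d_geom)
        hit_cyl = finite & (~interacted) & np.isfinite(d_cyl) & (d_cyl <= d_geom)
        hit_world = finite & (~interacted) & (~hit_cyl) & (d_world <= d_geom)
        hit_iface = finite & (~interacted) & (~hit_cyl) & (~hit_world)

        if record is not None and np.any(hit_cyl):
            p_hit = pos[hit_cyl] + dirs[hit_cyl] * d_cyl[hit_cyl, None]
            record.append(
                (
                    p_hit,
                    dirs[hit_cyl].copy(),
                    energy[hit_cyl].copy(),
                    cyl_code[hit_cyl].copy(),
                )
            )

        # interface crossers continue with the remaining optical depth
        cont = hit_iface
        tau = tau - mu * step
        pos = pos + dirs * step[:, None]
        pos[cont, 2] += np.sign(dirs[cont, 2]) * _EPS  # nudge into the new medium

        ipos, idirs, ie = pos[interacted], dirs[interacted], energy[interacted]
        (spos, sdirs, se), (ppos, pdirs, pe) = (
            _interact(
                attenuation,
                ipos[:, 2] >= 0.0,
                ipos, idirs, ie,
                config.cutoff_MeV,
                rng,
            )
            if ie.size
            else ((np.empty((0, 3)), np.empty((0, 3)), np.empty(0)),) * 2
        )

        pos = np.concatenate([pos[cont], spos, ppos])
        dirs = np.concatenate([dirs[cont], sdirs, pdirs])
        energy = np.concatenate([energy[cont], se, pe])
        tau = np.concatenate(
            [tau[cont], rng.exponential(size=se.size + pe.size)]
        )


def run_field(
    config: FieldConfig,
    cylinder: CouplingCylinder | None = None,
    attenuation: dict | None = None,
    source_sampler=None,
    scorer=None,
    batch_size: int = 100_000,
    n_batches: int | None = None,
) -> FieldResult:
    """Run an environmental field simulation.

    Parameters
    ----------
    config
        World, media, source, histories, seed.
    cylinder
        Coupling cylinder to record on (ideal absorber); omit for kerma runs.
    attenuation
        ``{"air": AttenuationTable | None, "soil": ...}``; ``None`` entries
        mean vacuum (zero attenuation).  Default: synthetic tables.
    source_sampler
        Optional ``f(rng, n) -> (pos, dirs, energies)`` overriding the
        configured source (used by geometry sanity tests).
    scorer
        Optional kerma tally receiving every in-air flight leg.

    Reproducible for a fixed ``config.seed``.
    """
    if attenuation is None:
        attenuation = default_attenuation(config)
    rng = np.random.default_rng(config.seed)
    record: list = []
    remaining = config.histories
    batch_index = 0
    while remaining > 0:
        n = min(batch_size, remaining)
        if source_sampler is not None:
            pos, dirs, energy = source_sampler(rng, n)
            pos = np.asarray(pos, float).reshape(n, 3).copy()
            dirs = np.asarray(dirs, float).reshape(n, 3).copy()
            energy = np.asarray(energy, float).reshape(n).copy()
        else:
            pos, dirs, energy = _sample_source(config, rng, n)
        _transport_batch(
            config, attenuation, cylinder, pos, dirs, energy, rng,
            record if cylinder is not None else None,
            scorer=scorer, batch_index=batch_index,
        )
        remaining -= n
        batch_index += 1

    if record:
        p = np.concatenate([r[0] for r in record])
        d = np.concatenate([r[1] for r in record])
        e = np.concatenate([r[2] for r in record])
        s = np.concatenate([r[3] for r in record])
    else:
        p = np.empty((0, 3))
        d = np.empty((0, 3))
        e = np.empty(0)
        s = np.empty(0, dtype=np.int8)
    crossings = pd.DataFrame(
        {
            "x": p[:, 0], "y": p[:, 1], "z": p[:, 2],
            "u": d[:, 0], "v": d[:, 1], "w": d[:, 2],
            "E": e,
            "weight": np.ones(e.size),
            "surface": [_SURFACE_NAMES[int(c)] for c in s],
        }
    )
    return FieldResult(config, cylinder, crossings, config.histories)


def free_path_lengths(
    table: AttenuationTable, energy_mev, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Sample analog free path lengths (m) from the total attenuation.

    This is the same exponential-in-optical-depth sampling the batch engine
    and :func:`transport_photon` use; exposed so the closed-form
    exp(-mu t) transmission law can be checked directly.
    """
    e = np.asarray(energy_mev, float)
    if e.ndim == 0:
        e = np.full(int(n), float(e))
    mu = table.mu_total(e)
    return rng.exponential(size=e.size) / mu


@dataclass(frozen=True)
class PhotonEvent:
    """Outcome of one transport step of a single photon."""

    kind: str  # "photoelectric" | "compton" | "pair" | "cutoff"
    position: np.ndarray
    direction: np.ndarray
    energy: float
    secondaries: tuple = ()


def transport_photon(
    position,
    direction,
    energy: float,
    table: AttenuationTable,
    rng: np.random.Generator,
    cutoff: float = 0.002,
) -> PhotonEvent:
    """One analog step in an infinite homogeneous medium.

    Samples the free path from the total attenuation coefficient, moves the
    photon, picks the interaction from the partial-coefficient ratios and
    applies it.  Compton results below the cutoff terminate with kind
    ``"cutoff"``.  Energies without attenuation data raise.
    """
    if energy <= cutoff:
        raise ValueError("photon energy must exceed the cutoff")
    pos = np.asarray(position, float)
    dirs = np.asarray(direction, float).reshape(1, 3)
    path = float(free_path_lengths(table, energy, rng, 1)[0])
    new_pos = pos + dirs[0] * path
    pe, inc, pp = (float(v[0]) for v in table.partials(energy))
    tot = pe + inc + pp
    xi = rng.random()
    if xi < pe / tot:
        return PhotonEvent("photoelectric", new_pos, dirs[0], 0.0)
    if xi < (pe + inc) / tot:
        cos_t, e_new = sample_klein_nishina(rng, np.array([energy]))
        new_dir = rotate_directions(rng, dirs, cos_t)[0]
        if e_new[0] < cutoff:
            return PhotonEvent("cutoff", new_pos, new_dir, float(e_new[0]))
        return PhotonEvent("compton", new_pos, new_dir, float(e_new[0]))
    secondaries = tuple(
        (new_pos.copy(), _isotropic(rng, 1)[0], _ANNIHILATION_MEV) for _ in range(2)
    )
    return PhotonEvent("pair", new_pos, dirs[0], 0.0, secondaries)
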
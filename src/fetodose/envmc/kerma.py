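"""Air kerma free-in-air at 1 m height from a track-length estimator.

The scoring region is a 30 cm diameter sphere of air centered 1 m above the
ground; the track-length fluence estimate in the sphere is converted to
kerma with the dry-air mass energy-transfer coefficient,

    K = sum_segments (l / V) * E * (mu_tr / rho),

per source particle and per unit activity concentration.

Because the environmental source is an infinite uniform plane (or a uniform
air volume), the field is invariant under horizontal translation, so the
track length may be integrated analytically over every lateral position of
the sphere: a straight flight leg from z0 to z1 of length L contributes

    integral A(z) ds,   A(z) = pi (R^2 - (z - z_c)^2)  for |z - z_c| < R,

the sphere's horizontal cross-section area along the leg.  Dividing by the
sphere volume gives the fluence per unit areal source intensity directly —
an exact variance reduction, equivalent to averaging the conventional
single-sphere tally over all sphere positions at 1 m height.  The source is
then sampled as a point (or a vertical column, for the air-volume case) on
the world axis.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .engine import FieldConfig, run_field
from .materials import air_mu_tr_table

__all__ = [
    "KermaTally",
    "air_kerma_at_1m",
    "kerma_from_fluence",
    "estimate_kerma_coefficient",
]

MEV_TO_J = 1.602176634e-13
CM2_PER_G_TO_M2_PER_KG = 0.1


def _mu_tr_interp(mu_tr_table):
    e = np.asarray(mu_tr_table["energy_MeV"], float)
    m = np.asarray(mu_tr_table["mu_tr_over_rho"], float)
    loge, logm = np.log(e), np.log(m)

    def f(energy):
        return np.exp(np.interp(np.log(np.asarray(energy, float)), loge, logm))

    return f


class KermaTally:
    """Accumulates translation-integrated track lengths in the scoring sphere.

    ``score`` receives every in-air flight leg (energy, start z, end z,
    length); contributions are kept per batch so a standard error can be
    formed from the batch scatter.
    """

    def __init__(self, center_height_m: float = 1.0, radius_m: float = 0.15):
        self.center = center_height_m
        self.radius = radius_m
        self.volume = 4.0 / 3.0 * np.pi * radius_m**3
        self._batch_sums: dict[int, float] = {}
        self._energies: list[np.ndarray] = []
        self._contribs: list[np.ndarray] = []
        self._batches: list[np.ndarray] = []

    def score(self, energy, z0, z1, length, batch_index: int) -> None:
        contrib = self._area_integral(
            np.asarray(z0, float), np.asarray(z1, float), np.asarray(length, float)
        )
        keep = contrib > 0
        if not np.any(keep):
            return
        self._energies.append(np.asarray(energy, float)[keep])
        self._contribs.append(contrib[keep])
        self._batches.append(np.full(int(keep.sum()), batch_index, dtype=np.int64))

    def _area_integral(self, z0, z1, length) -> np.ndarray:
        """integral of pi (R^2 - (z - c)^2) ds along each leg (m^3)."""
        c, r = self.center, self.radius
        lo = np.minimum(z0, z1)
        hi = np.maximum(z0, z1)
        za = np.maximum(lo, c - r)
        zb = np.minimum(hi, c + r)
        dz = hi - lo
        out = np.zeros_like(z0)
        horiz = dz < 1e-12
        inside = horiz & (np.abs(z0 - c) < r)
        out[inside] = np.pi * (r**2 - (z0[inside] - c) ** 2) * length[inside]
        sl = (~horiz) & (zb > za)
        if np.any(sl):
            def prim(z):
                return r**2 * z - (z - c) ** 3 / 3.0
            integ_z = prim(zb[sl]) - prim(za[sl])  # integral over dz
            out[sl] = np.pi * integ_z * length[sl] / dz[sl]
        return out

    @property
    def n_scores(self) -> int:
        return sum(a.size for a in self._contribs)


def kerma_from_fluence(fluence_per_m2: float, energy_mev: float, mu_tr_over_rho: float) -> float:
    """Closed-form kerma (Gy) for a uniform fluence: K = Phi * E * mu_tr/rho."""
    return fluence_per_m2 * energy_mev * MEV_TO_J * mu_tr_over_rho * CM2_PER_G_TO_M2_PER_KG


def air_kerma_at_1m(
    tally: KermaTally,
    mu_tr_table,
    histories: int,
    source_norm: float = 1.0,
    n_batches: int | None = None,
):
    """Convert a tally into the kerma rate coefficient with its standard error.

    ``source_norm`` converts per-source-particle to per unit activity
    concentration (1 for a plane source per Bq m-2; the source column height
    for a uniform volume source per Bq m-3).

    Returns (coefficient, standard_error); an empty tally yields (0, nan)
    with a warning.
    """
    if tally.n_scores == 0:
        warnings.warn("empty kerma tally: no track crossed the scoring region")
        return 0.0, float("nan")
    mu_tr = _mu_tr_interp(mu_tr_table)
    e = np.concatenate(tally._energies)
    c = np.concatenate(tally._contribs)
    b = np.concatenate(tally._batches)
    per_score = (
        c / tally.volume
        * e * MEV_TO_J
        * mu_tr(e) * CM2_PER_G_TO_M2_PER_KG
        * source_norm
    )
    total = per_score.sum() / histories
    nb = n_batches if n_batches is not None else int(b.max()) + 1
    if nb > 1:
        batch_totals = np.bincount(b, weights=per_score, minlength=nb)
        per_hist = histories / nb
        means = batch_totals / per_hist
        stderr = float(means.std(ddof=1) / np.sqrt(nb))
    else:
        stderr = float("nan")
    return float(total), stderr


def estimate_kerma_coefficient(
    config: FieldConfig,
    attenuation: dict | None = None,
    mu_tr_table=None,
    center_height_m: float = 1.0,
    radius_m: float = 0.15,
    batch_size: int = 50_000,
):
    """Run the field and estimate the air kerma rate coefficient at 1 m.

    Ground geometry returns Gy s-1 Bq-1 m2, air-volume Gy s-1 Bq-1 m3.
    Reproducible for fixed ``config.seed``.
    """
    if mu_tr_table is None:
        mu_tr_table = air_mu_tr_table()
    # keep at least ~10 batches so a batch-scatter standard error exists
    batch_size = max(1, min(batch_size, -(-config.histories // 10)))
    tally = KermaTally(center_height_m, radius_m)

    def axis_source(rng, n):
        # lateral position is irrelevant under the translation-folded tally;
        # keep the source on the axis so the world boundary is centered on it
        if config.source == "ground_plane":
            z = np.full(n, -config.source_depth_m)
        else:
            z = rng.uniform(0.0, config.effective_source_height_m, n)
        pos = np.column_stack([np.zeros(n), np.zeros(n), z])
        w = rng.uniform(-1.0, 1.0, n)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        s = np.sqrt(1.0 - w**2)
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), w])
        return pos, dirs, np.full(n, config.energy_MeV)

    run_field(
        config,
        cylinder=None,
        attenuation=attenuation,
        source_sampler=axis_source,
        scorer=tally,
        batch_size=batch_size,
    )
    source_norm = (
        1.0 if config.source == "ground_plane" else config.effective_source_height_m
    )
    n_batches = -(-config.histories // batch_size)
    return air_kerma_at_1m(
        tally, mu_tr_table, config.histories, source_norm, n_batches
    )
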
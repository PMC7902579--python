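"""Coupling-cylinder phase-space probability density functions.

Crossings recorded on the coupling cylinder are condensed into discrete
densities p_S(cos theta, h, E) on the side and p_L(cos theta, E) on the
lids.  Because the environmental field is invariant under rotation about the
cylinder axis and horizontal translation, the azimuthal position/direction
and the lid radius carry no information and are dropped; resampling restores
them uniformly.  Bin widths follow the published choice: 0.1 in cos theta,
10 cm in height, and the per-decade energy grid with mantissas
1.0, 1.5, 2, 3, 4, 5, 6, 7, 8, 9.  All bins are half-open [low, high) with
the final bin closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseSpacePDF",
    "decade_energy_edges",
    "bin_phase_space",
    "sample_phase_space",
]

_DECADE_MANTISSAS = np.array([1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])

COS_BIN_WIDTH = 0.1
H_BIN_WIDTH_M = 0.10


def decade_energy_edges(e_low: float, e_high: float) -> np.ndarray:
    """Per-decade energy bin edges spanning [e_low, e_high] (MeV)."""
    if not 0 < e_low < e_high:
        raise ValueError("need 0 < e_low < e_high")
    dec_lo = int(np.floor(np.log10(e_low)))
    dec_hi = int(np.ceil(np.log10(e_high)))
    edges = np.concatenate(
        [np.round(_DECADE_MANTISSAS * 10.0**d, 12) for d in range(dec_lo, dec_hi + 1)]
    )
    lo_idx = np.searchsorted(edges, e_low, side="right") - 1
    hi_idx = np.searchsorted(edges, e_high, side="left")
    return edges[max(lo_idx, 0): hi_idx + 1]


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [low, high) binning with the final bin closed above."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = edges.size - 2
    return idx


@dataclass
class PhaseSpacePDF:
    """Normalized binned emission densities on the coupling cylinder.

    ``side_prob`` has shape (n_cos, n_h, n_E) and ``lid_prob`` (n_cos, n_E);
    together they sum to 1.  ``side_err``/``lid_err`` are per-bin binomial
    standard errors of the probabilities.  cos(theta) is measured against
    the upward vertical axis; h is the height above the cylinder base.
    """

    cos_edges: np.ndarray
    h_edges: np.ndarray
    e_edges: np.ndarray
    side_counts: np.ndarray
    lid_counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("phase-space PDF needs at least one crossing")
        if self.side_counts.sum() + self.lid_counts.sum() != self.n_total:
            raise ValueError("counts do not add up to the crossing total")

    @property
    def side_prob(self) -> np.ndarray:
        return self.side_counts / self.n_total

    @property
    def lid_prob(self) -> np.ndarray:
        return self.lid_counts / self.n_total

    def _binomial_err(self, counts: np.ndarray) -> np.ndarray:
        p = counts / self.n_total
        return np.sqrt(p * (1.0 - p) / self.n_total)

    @property
    def side_err(self) -> np.ndarray:
        return self._binomial_err(self.side_counts)

    @property
    def lid_err(self) -> np.ndarray:
        return self._binomial_err(self.lid_counts)

    @property
    def total_probability(self) -> float:
        return float(self.side_prob.sum() + self.lid_prob.sum())

    def to_json(self, path=None) -> str:
        payload = {
            "cos_edges": self.cos_edges.tolist(),
            "h_edges": self.h_edges.tolist(),
            "e_edges": self.e_edges.tolist(),
            "side_counts": self.side_counts.tolist(),
            "lid_counts": self.lid_counts.tolist(),
            "n_total": self.n_total,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PhaseSpacePDF":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            s = str(source)
            if s.lstrip().startswith("{"):
                payload = json.loads(s)
            else:
                with open(source, "r", encoding="utf-8") as fh:
                    payload = json.load(fh)
        return cls(
            np.asarray(payload["cos_edges"]),
            np.asarray(payload["h_edges"]),
            np.asarray(payload["e_edges"]),
            np.asarray(payload["side_counts"]),
            np.asarray(payload["lid_counts"]),
            int(payload["n_total"]),
        )


def bin_phase_space(
    crossings,
    cylinder,
    source_energy: float,
    cutoff: float = 0.002,
) -> PhaseSpacePDF:
    """Bin a crossing log into the normalized phase-space densities.

    ``crossings`` is the DataFrame produced by the field run (columns z, w,
    E, surface).  Bottom-lid entries are pooled with the lid density.
    Crossings off the cylinder surface or above the source energy are
    errors.
    """
    n = len(crossings)
    if n < 1:
        raise ValueError("need at least one crossing to build a PDF")
    e = np.asarray(crossings["E"], float)
    if np.any(e > source_energy * (1 + 1e-9)):
        raise ValueError("crossing energy exceeds the source energy")
    z = np.asarray(crossings["z"], float)
    w = np.asarray(crossings["w"], float)
    surface = np.asarray(crossings["surface"], dtype=object)
    on_side = surface == "side"
    if np.any((z < -1e-6) | (z > cylinder.height_m + 1e-6)):
        raise ValueError("crossing outside the cylinder surface")

    cos_edges = np.round(np.arange(-10, 11) * COS_BIN_WIDTH, 10)
    n_h = int(round(cylinder.height_m / H_BIN_WIDTH_M))
    h_edges = np.linspace(0.0, cylinder.height_m, n_h + 1)
    e_edges = decade_energy_edges(cutoff, source_energy)

    ic = _bin_index(np.clip(w, -1.0, 1.0), cos_edges)
    ie = _bin_index(e, e_edges)
    side_counts = np.zeros((20, n_h, e_edges.size - 1), dtype=np.int64)
    lid_counts = np.zeros((20, e_edges.size - 1), dtype=np.int64)
    ih = _bin_index(np.clip(z[on_side], 0.0, cylinder.height_m), h_edges)
    np.add.at(side_counts, (ic[on_side], ih, ie[on_side]), 1)
    np.add.at(lid_counts, (ic[~on_side], ie[~on_side]), 1)
    return PhaseSpacePDF(cos_edges, h_edges, e_edges, side_counts, lid_counts, n)


def sample_phase_space(
    pdf: PhaseSpacePDF,
    rng: np.random.Generator,
    n: int,
    cylinder,
):
    """Draw ``n`` particle states on the cylinder surface from the PDF.

    Binned attributes (cos theta, h, E) are sampled from the discrete
    densities and smeared uniformly within their bins; the coordinates the
    rotational-invariance argument drops are restored uniformly: azimuthal
    position and direction angles on [0, 2 pi), lid radius area-uniform.

    Returns a dict of arrays: x, y, z, u, v, w, E, surface.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    side_p = pdf.side_prob.ravel()
    lid_p = pdf.lid_prob.ravel()
    probs = np.concatenate([side_p, lid_p])
    idx = rng.choice(probs.size, size=n, p=probs / probs.sum())
    is_side = idx < side_p.size

    n_cos = pdf.cos_edges.size - 1
    n_h = pdf.h_edges.size - 1
    n_e = pdf.e_edges.size - 1

    cos_t = np.empty(n)
    e_out = np.empty(n)
    z = np.empty(n)
    x = np.empty(n)
    y = np.empty(n)

    def _uniform_in(edges, bins, m):
        lo = edges[bins]
        hi = edges[bins + 1]
        return rng.uniform(size=m) * (hi - lo) + lo

    si = idx[is_side]
    ic, ih, ie = np.unravel_index(si, (n_cos, n_h, n_e))
    m = si.size
    cos_t[is_side] = _uniform_in(pdf.cos_edges, ic, m)
    z[is_side] = _uniform_in(pdf.h_edges, ih, m)
    e_out[is_side] = _uniform_in(pdf.e_edges, ie, m)
    beta = rng.uniform(0.0, 2.0 * np.pi, m)
    x[is_side] = cylinder.radius_m * np.cos(beta)
    y[is_side] = cylinder.radius_m * np.sin(beta)

    li = idx[~is_side] - side_p.size
    ic_l, ie_l = np.unravel_index(li, (n_cos, n_e))
    m_l = li.size
    cos_t[~is_side] = _uniform_in(pdf.cos_edges, ic_l, m_l)
    e_out[~is_side] = _uniform_in(pdf.e_edges, ie_l, m_l)
    z[~is_side] = cylinder.height_m
    rho = cylinder.radius_m * np.sqrt(rng.uniform(size=m_l))  # area-uniform
    beta_l = rng.uniform(0.0, 2.0 * np.pi, m_l)
    x[~is_side] = rho * np.cos(beta_l)
    y[~is_side] = rho * np.sin(beta_l)

    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    u = sin_t * np.cos(phi)
    v = sin_t * np.sin(phi)
    surface = np.where(is_side, "side", "lid")
    return {
        "x": x, "y": y, "z": z, "u": u, "v": v, "w": cos_t,
        "E": e_out, "surface": surface,
    }
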
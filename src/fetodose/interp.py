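"""Monotone piecewise cubic Hermite interpolation of coefficient tables.

The monoenergetic coefficient tables are interpolated with the classic
monotonicity-preserving cubic Hermite scheme of Fritsch and Carlson, applied
in a log-linear space: the abscissa is log10 of the photon energy in MeV, the
ordinate is the coefficient itself.  Because the underlying field
calculations start at 0.015 MeV, the interpolant is defined to be exactly
zero below that cutoff; above 10 MeV no extrapolation is performed and
evaluation is an error.

The node-derivative rule: where adjacent secant slopes differ in sign or
either vanishes, the derivative is zero (the node is a local extremum);
otherwise it is the Brodlie weighted harmonic mean of the two secants,

    d_k = (w1 + w2) / (w1/s_{k-1} + w2/s_k),
    w1 = 2 h_k + h_{k-1},  w2 = h_k + 2 h_{k-1},

which always lies inside the Fritsch-Carlson monotonicity region, so each
data-monotone segment yields a monotone interpolant with no overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_tables import CoefficientTable, E_MAX

__all__ = [
    "fc_derivatives",
    "make_curve",
    "evaluate",
    "DoseCoefficientCurve",
    "EnergyRangeError",
]

#: Coefficients below this photon energy are defined to be zero (MeV).
CUTOFF_MEV = 0.015


class EnergyRangeError(ValueError):
    """Requested evaluation energy outside the curve's defined domain."""


def fc_derivatives(x, y) -> np.ndarray:
    """Per-node slopes of the Fritsch-Carlson monotone cubic Hermite scheme.

    Parameters
    ----------
    x, y
        Ordered data; ``x`` strictly increasing, at least 2 points.

    Returns
    -------
    numpy.ndarray
        One slope per node.  For two points, both slopes equal the secant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("need at least 2 nodes")
    h = np.diff(x)
    if np.any(h <= 0):
        raise ValueError("x must be strictly increasing (duplicates not allowed)")
    s = np.diff(y) / h
    n = x.size
    d = np.zeros(n)
    if n == 2:
        return np.full(2, s[0])

    # interior nodes: zero at sign changes / flat secants, else the Brodlie
    # weighted harmonic mean of the adjacent secants
    sl, sr = s[:-1], s[1:]
    hl, hr = h[:-1], h[1:]
    mono = (sl * sr) > 0
    w1 = 2.0 * hr + hl
    w2 = hr + 2.0 * hl
    with np.errstate(divide="ignore", invalid="ignore"):
        hmean = (w1 + w2) / (w1 / np.where(mono, sl, 1.0) + w2 / np.where(mono, sr, 1.0))
    d[1:-1] = np.where(mono, hmean, 0.0)

    d[0] = _edge_slope(h[0], h[1], s[0], s[1])
    d[-1] = _edge_slope(h[-1], h[-2], s[-1], s[-2])
    return d


def _edge_slope(h0, h1, s0, s1) -> float:
    """Shape-preserving three-point end slope (one-sided parabola, clipped)."""
    d = ((2.0 * h0 + h1) * s0 - h0 * s1) / (h0 + h1)
    if np.sign(d) != np.sign(s0):
        return 0.0
    if np.sign(s0) != np.sign(s1) and abs(d) > 3.0 * abs(s0):
        return 3.0 * s0
    return float(d)


_X_TRANSFORMS = {
    "log10": (np.log10, "log10(E/MeV)"),
    "linear": (lambda e: np.asarray(e, float), "E/MeV"),
}


@dataclass(frozen=True)
class DoseCoefficientCurve:
    """Monotone Hermite interpolant of one coefficient table.

    The curve reproduces every table node exactly, returns 0 below the
    0.015 MeV cutoff, and refuses to extrapolate: energies above 10 MeV or
    inside the gap between the cutoff and a first node above the cutoff
    raise :class:`EnergyRangeError`.

    ``x_scale``/``y_scale`` record the interpolation space.  The default
    (``"log10"``, ``"linear"``) is the standard reading of "log-linear" in
    dosimetric tabulation; ``y_scale="log10"`` is available so the two
    conventions can be compared (zero-valued nodes are then not allowed).
    """

    source_table: CoefficientTable
    abscissa: np.ndarray
    ordinate: np.ndarray
    node_derivatives: np.ndarray
    x_scale: str = "log10"
    y_scale: str = "linear"
    cutoff: float = CUTOFF_MEV

    @property
    def e_min(self) -> float:
        return float(self.source_table.energies[0])

    @property
    def e_max(self) -> float:
        return float(self.source_table.energies[-1])

    def __call__(self, energy):
        return evaluate(self, energy)

    def evaluate(self, energy):
        return evaluate(self, energy)


def make_curve(
    table: CoefficientTable,
    x_scale: str = "log10",
    y_scale: str = "linear",
) -> DoseCoefficientCurve:
    """Build the monotone interpolant of ``table``.

    Raises
    ------
    ValueError
        Fewer than 2 nodes, unknown scale, or log ordinate with zero values.
    """
    if x_scale not in _X_TRANSFORMS:
        raise ValueError(f"unknown x_scale {x_scale!r}")
    if y_scale not in ("linear", "log10"):
        raise ValueError(f"unknown y_scale {y_scale!r}")
    xt = _X_TRANSFORMS[x_scale][0](table.energies)
    if y_scale == "log10":
        if np.any(table.values <= 0):
            raise ValueError("log10 ordinate requires strictly positive values")
        yt = np.log10(table.values)
    else:
        yt = table.values.copy()
    d = fc_derivatives(xt, yt)
    return DoseCoefficientCurve(table, xt, yt, d, x_scale, y_scale)


def _hermite(xq, x, y, d):
    """Vectorized cubic Hermite evaluation on a node grid with slopes d."""
    k = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, x.size - 2)
    h = x[k + 1] - x[k]
    t = (xq - x[k]) / h
    h00 = (1 + 2 * t) * (1 - t) ** 2
    h10 = t * (1 - t) ** 2
    h01 = t * t * (3 - 2 * t)
    h11 = t * t * (t - 1)
    return h00 * y[k] + h10 * h * d[k] + h01 * y[k + 1] + h11 * h * d[k + 1]


def evaluate(curve: DoseCoefficientCurve, energy):
    """Coefficient at ``energy`` (MeV); scalar or array.

    Rules: exact at nodes; 0 below the 0.015 MeV cutoff; errors for
    non-positive energies, energies above 10 MeV, energies above the last
    node, and energies between the cutoff and a first node above the cutoff.
    """
    e = np.asarray(energy, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    if np.any(e <= 0):
        raise EnergyRangeError("photon energy must be positive")
    if np.any(e > E_MAX + 1e-12):
        raise EnergyRangeError(f"no extrapolation above {E_MAX} MeV")
    out = np.zeros_like(e)
    live = e >= curve.cutoff
    if np.any(live):
        if np.any(e[live] < curve.e_min - 1e-12):
            raise EnergyRangeError(
                f"energy below the first table node ({curve.e_min} MeV) but at or "
                f"above the {curve.cutoff} MeV cutoff: undefined, not zero"
            )
        if np.any(e[live] > curve.e_max + 1e-12):
            raise EnergyRangeError(
                f"no extrapolation above the last table node ({curve.e_max} MeV)"
            )
        xq = _X_TRANSFORMS[curve.x_scale][0](e[live])
        vals = _hermite(xq, curve.abscissa, curve.ordinate, curve.node_derivatives)
        if curve.y_scale == "log10":
            vals = 10.0 ** vals
        out[live] = np.maximum(vals, 0.0)
    return float(out[0]) if scalar else out
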
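"""Compton scattering kinematics: Klein-Nishina sampling and the analytic
angular distribution used as the test oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_klein_nishina", "kn_cos_theta_pdf", "rotate_directions"]

_ELECTRON_REST_MEV = 0.511


def sample_klein_nishina(rng: np.random.Generator, energy_mev, n: int | None = None):
    """Sample Compton scatters from the Klein-Nishina distribution.

    Uses the standard composition-rejection sampling of the energy-ratio
    distribution (mixture of a 1/eps part and a flat-in-eps^2 part, with the
    sin^2 rejection factor).

    Parameters
    ----------
    energy_mev
        Scalar energy with ``n`` samples, or an array of per-photon energies
        (one sample each, ``n`` ignored).

    Returns
    -------
    (cos_theta, e_out) : arrays
    """
    e = np.asarray(energy_mev, float)
    if e.ndim == 0:
        e = np.full(int(n), float(e))
    a = e / _ELECTRON_REST_MEV
    eps0 = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    eps = np.empty(e.size)
    todo = np.arange(e.size)
    while todo.size:
        at, a1t, a2t, e0t = a[todo], a1[todo], a2[todo], eps0[todo]
        r1 = rng.random(todo.size)
        r2 = rng.random(todo.size)
        r3 = rng.random(todo.size)
        cand = np.where(
            r1 < a1t / (a1t + a2t),
            np.exp(-a1t * r2),  # ~ 1/eps on [eps0, 1]
            np.sqrt(e0t**2 + (1.0 - e0t**2) * r2),  # ~ eps on [eps0, 1]
        )
        t = (1.0 - cand) / (at * cand)
        sin2 = t * (2.0 - t)
        accept = r3 < 1.0 - cand * sin2 / (1.0 + cand**2)
        eps[todo[accept]] = cand[accept]
        todo = todo[~accept]
    cos_theta = 1.0 - (1.0 - eps) / (a * eps)
    return cos_theta, eps * e


def kn_cos_theta_pdf(energy_mev: float, cos_theta) -> np.ndarray:
    """Unnormalized Klein-Nishina density in cos(theta) at one energy.

    d sigma / d cos(theta) ~ eps^2 (eps + 1/eps - sin^2 theta),
    eps = 1 / (1 + a (1 - cos theta)).  Normalize numerically when a
    probability density is needed.
    """
    a = energy_mev / _ELECTRON_REST_MEV
    mu = np.asarray(cos_theta, float)
    eps = 1.0 / (1.0 + a * (1.0 - mu))
    return eps**2 * (eps + 1.0 / eps - (1.0 - mu**2))


def rotate_directions(rng: np.random.Generator, directions: np.ndarray, cos_theta: np.ndarray):
    """Rotate unit vectors by polar angle acos(cos_theta) and a uniform azimuth."""
    u = directions
    n = u.shape[0]
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_theta**2))
    # build an orthonormal frame around each direction
    w = u
    helper = np.where(
        np.abs(w[:, 2:3]) < 0.99, np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]])
    )
    e1 = np.cross(w, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(w, e1)
    out = (
        w * cos_theta[:, None]
        + e1 * (sin_t * np.cos(phi))[:, None]
        + e2 * (sin_t * np.sin(phi))[:, None]
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)
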
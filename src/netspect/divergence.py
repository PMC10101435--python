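"""Kullback–Leibler and Jensen–Shannon divergences between spectral densities.

The KL integral is discretized as a Riemann (trapezoid-weight) sum.  Both
densities are first converted to discrete probability masses on the shared
grid and renormalized, so the discretized KL is a true discrete KL and the
Gibbs inequality guarantees nonnegativity.  Natural logarithms throughout;
the JS divergence is therefore bounded by ln 2, and its square root is a
metric (it satisfies the triangle inequality), which is the distance used
by the graph k-means.
"""

from __future__ import annotations

import math

import numpy as np

from .spectral import SpectralDensity

__all__ = [
    "kl_divergence",
    "js_divergence",
    "spectral_distance",
    "grid_masses",
    "kl_masses",
    "js_masses",
]

#: values below this floor are treated as exact zeros (underflow guard)
_FLOOR = 1e-300

LN2 = math.log(2.0)


def _check_grids(rho1: SpectralDensity, rho2: SpectralDensity) -> None:
    if not np.array_equal(rho1.grid, rho2.grid):
        raise ValueError("densities must be evaluated on the identical grid")


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    dx = np.diff(grid)
    w = np.empty_like(grid)
    w[0] = dx[0] / 2.0
    w[-1] = dx[-1] / 2.0
    w[1:-1] = (dx[:-1] + dx[1:]) / 2.0
    return w


def grid_masses(rho: SpectralDensity) -> np.ndarray:
    """Discrete probability masses of a density on its own grid."""
    p = rho.density * _trapezoid_weights(rho.grid)
    p = p / p.sum()
    p[p < _FLOOR] = 0.0
    return p


def kl_masses(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete KL between mass vectors; +inf on support violation."""
    mask = p > 0.0
    q_masked = q[mask]
    if np.any(q_masked <= 0.0):
        return math.inf
    val = float(np.sum(p[mask] * np.log(p[mask] / q_masked)))
    return max(val, 0.0)


def js_masses(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete JS between mass vectors (always finite, ≤ ln 2)."""
    m = 0.5 * (p + q)
    return 0.5 * kl_masses(p, m) + 0.5 * kl_masses(q, m)


def kl_divergence(rho1: SpectralDensity, rho2: SpectralDensity) -> float:
    """KL(ρ₁ | ρ₂) by Riemann sum; +inf when ρ₂'s support misses mass of ρ₁.

    Grid points where ρ₁ = 0 contribute zero regardless of ρ₂.
    """
    _check_grids(rho1, rho2)
    return kl_masses(grid_masses(rho1), grid_masses(rho2))


def js_divergence(rho1: SpectralDensity, rho2: SpectralDensity) -> float:
    """Symmetric Jensen–Shannon divergence via the mixture ½(ρ₁ + ρ₂)."""
    _check_grids(rho1, rho2)
    return js_masses(grid_masses(rho1), grid_masses(rho2))


def spectral_distance(rho1: SpectralDensity, rho2: SpectralDensity) -> float:
    """√JS — a metric between spectral densities."""
    return math.sqrt(js_divergence(rho1, rho2))
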
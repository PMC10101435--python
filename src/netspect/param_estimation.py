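"""KL-minimizing parameter estimation for random graph models.

Closed-form spectral densities are unknown for most random-graph
families, so the model density ρ_M(θ) is approximated by Monte Carlo:
the mean spectral density of (by default) 50 independent draws from the
model at parameter θ, generated at the *same size* as the graph being
fitted.  The estimator is then a grid search

    θ̂ = argmin_θ KL(ρ_G | ρ_M(θ)),

and model selection between candidate families picks the family whose
best-grid KL is smallest.

Monte-Carlo spectra are cached keyed by (model, θ, size, replicates) and
seeded deterministically from a master seed plus that key, so repeated
calls are bit-identical and independent of call order — essential for
the EM-style clustering loop that re-evaluates model densities heavily.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import graph_models as gm
from .divergence import grid_masses, kl_masses
from .spectral import (
    SpectralDensity,
    Spectrum,
    adjacency_spectrum,
    mean_density,
    shared_grid,
    spectral_density,
)

__all__ = [
    "GraphModelSpec",
    "EstimationResult",
    "EstimationFailedError",
    "model_mean_density",
    "estimate_parameter",
    "select_model",
    "default_grid",
]


class EstimationFailedError(RuntimeError):
    """Every grid point (or candidate model) yielded an infinite KL."""


def _theta_tuple(theta) -> Tuple[float, ...]:
    return tuple(float(v) for v in np.atleast_1d(theta))


def _theta_key(theta) -> Tuple[float, ...]:
    return tuple(round(v, 9) for v in _theta_tuple(theta))


def _even_clip(k: float, n: int) -> int:
    """Nearest even integer in [2, n-1)."""
    k = 2 * int(round(k / 2.0))
    return int(np.clip(k, 2, max(2, (n - 1) // 2 * 2)))


# --- model registry -------------------------------------------------------
# Each family lists its free-parameter names in order, a sampler taking
# (n, rng, **params), a projection mapping an arbitrary real parameter
# vector (e.g. a cluster mean) back into the model's legal domain at a
# given size, and a default search grid.

def _grid_er(n):
    return [round(p, 2) for p in np.arange(0.01, 1.00, 0.01)]


def _grid_gnm(n):
    total = n * (n - 1) // 2
    return sorted({int(v) for v in np.linspace(0, total, 21)})


def _grid_geom(n):
    return [round(r, 2) for r in np.arange(0.05, 1.00, 0.05)]


def _grid_kreg(n):
    return [k for k in range(2, min(n - 1, 20) + 1, 2)]


def _grid_ps(n):
    return [round(v, 2) for v in np.arange(0.5, 3.01, 0.25)]


_MODELS: Dict[str, dict] = {
    "erdos_renyi_gnp": dict(
        params=("p",),
        sampler=lambda n, rng, p: gm.erdos_renyi_gnp(n, p, rng),
        project=lambda theta, n, fixed: (float(np.clip(theta[0], 0.0, 1.0)),),
        default_grid=lambda n, fixed: _grid_er(n),
    ),
    "erdos_renyi_gnm": dict(
        params=("m",),
        sampler=lambda n, rng, m: gm.erdos_renyi_gnm(n, int(m), rng),
        project=lambda theta, n, fixed: (
            float(np.clip(round(theta[0]), 0, n * (n - 1) // 2)),
        ),
        default_grid=lambda n, fixed: _grid_gnm(n),
    ),
    "geometric": dict(
        params=("r",),
        sampler=lambda n, rng, r: gm.geometric_graph(n, r, rng),
        project=lambda theta, n, fixed: (float(np.clip(theta[0], 0.0, 1.5)),),
        default_grid=lambda n, fixed: _grid_geom(n),
    ),
    "k_regular": dict(
        params=("k",),
        sampler=lambda n, rng, k: gm.k_regular(n, int(k), rng),
        project=lambda theta, n, fixed: (
            float(_even_clip(theta[0], n) if n % 2 else
                  int(np.clip(round(theta[0]), 1, n - 1))),
        ),
        default_grid=lambda n, fixed: _grid_kreg(n),
    ),
    "watts_strogatz": dict(
        params=("k", "p"),
        sampler=lambda n, rng, k, p: gm.watts_strogatz(n, int(k), p, rng),
        project=lambda theta, n, fixed: tuple(
            (float(_even_clip(v, n)) if name == "k" else float(np.clip(v, 0.0, 1.0)))
            for name, v in theta.items()
        ),
        default_grid=lambda n, fixed: (
            [round(p, 2) for p in np.arange(0.0, 1.001, 0.05)]
            if "k" in fixed
            else [(k, round(p, 2)) for k in _grid_kreg(n)
                  for p in np.arange(0.0, 1.001, 0.05)]
        ),
    ),
    "preferential_attachment": dict(
        params=("m", "ps"),
        sampler=lambda n, rng, m, ps: gm.preferential_attachment(n, int(m), ps, rng),
        project=lambda theta, n, fixed: tuple(
            (float(np.clip(round(v), 1, n)) if name == "m" else float(v))
            for name, v in theta.items()
        ),
        default_grid=lambda n, fixed: (
            _grid_ps(n) if "m" in fixed
            else [(m, ps) for m in (2, 5, 10) for ps in _grid_ps(n)]
        ),
    ),
}


@dataclass
class GraphModelSpec:
    """A random-graph family, optional fixed parameters, and a search grid.

    ``theta`` holds the free parameter(s) (scalar, or tuple for 2-D
    families like Watts–Strogatz with neither k nor p fixed); ``fixed``
    pins named parameters (e.g. ``fixed={"k": 16}`` estimates only the
    rewiring probability).  ``grid`` lists candidate theta values for
    estimation; when omitted, a family default is used.
    """

    model_id: str
    theta: object = None
    grid: Optional[Sequence] = None
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.model_id not in _MODELS:
            raise ValueError(f"unknown model {self.model_id!r}; "
                             f"choose from {sorted(_MODELS)}")
        bad = set(self.fixed) - set(_MODELS[self.model_id]["params"])
        if bad:
            raise ValueError(f"unknown fixed parameters {sorted(bad)}")

    @property
    def free_params(self) -> Tuple[str, ...]:
        return tuple(
            p for p in _MODELS[self.model_id]["params"] if p not in self.fixed
        )

    def cache_key(self):
        return (self.model_id, tuple(sorted(self.fixed.items())))

    def sample(self, theta, n: int, seed=None) -> gm.Graph:
        """Draw one graph of size ``n`` at free parameter(s) ``theta``."""
        values = _theta_tuple(theta)
        if len(values) != len(self.free_params):
            raise ValueError(
                f"theta has {len(values)} values, model expects "
                f"{len(self.free_params)} ({self.free_params})"
            )
        kwargs = dict(self.fixed)
        kwargs.update(zip(self.free_params, values))
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return _MODELS[self.model_id]["sampler"](n, rng, **kwargs)

    def project(self, theta, n: int):
        """Map an arbitrary real theta (e.g. a cluster mean) into the
        model's legal domain at size ``n`` (clipping, parity rounding)."""
        values = _theta_tuple(theta)
        entry = _MODELS[self.model_id]
        if self.model_id in ("watts_strogatz", "preferential_attachment"):
            named = dict(zip(self.free_params, values))
            out = entry["project"](named, n, self.fixed)
        else:
            out = entry["project"](values, n, self.fixed)
        return out[0] if len(out) == 1 else tuple(out)

    def grid_for(self, n: int) -> List:
        if self.grid is not None:
            return list(self.grid)
        return list(_MODELS[self.model_id]["default_grid"](n, self.fixed))


def default_grid(model_id: str, n: int, fixed: Mapping[str, float] = ()) -> List:
    """The family's default parameter search grid at size ``n``."""
    return GraphModelSpec(model_id, fixed=dict(fixed)).grid_for(n)


@dataclass
class EstimationResult:
    """Grid-search result of the KL-minimizing estimator."""

    theta_hat: object
    kl_min: float
    thetas: List
    grid_kl: np.ndarray
    n_mc: int
    size: int


def _derived_rng(seed: int, key) -> np.random.Generator:
    """Deterministic child RNG from a master seed and a hashable key."""
    h = zlib.crc32(repr(key).encode()) & 0x7FFFFFFF
    master = int(seed) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master, h]))


def model_spectra(
    model: GraphModelSpec,
    theta,
    n: int,
    n_mc: int = 50,
    seed: int = 0,
    cache: Optional[dict] = None,
) -> List[Spectrum]:
    """Spectra of ``n_mc`` independent model draws at size ``n``.

    The RNG stream is derived from (seed, model, θ, n, n_mc), so results
    do not depend on the order in which combinations are requested.
    """
    key = (model.cache_key(), _theta_key(theta), int(n), int(n_mc))
    if cache is not None and key in cache:
        return cache[key]
    rng = _derived_rng(seed, key)
    spectra = [adjacency_spectrum(model.sample(theta, n, rng)) for _ in range(n_mc)]
    if cache is not None:
        cache[key] = spectra
    return spectra


def model_mean_density(
    model: GraphModelSpec,
    theta,
    n: int,
    grid: np.ndarray,
    n_mc: int = 50,
    seed: int = 0,
    cache: Optional[dict] = None,
) -> SpectralDensity:
    """Monte-Carlo model density: mean of ``n_mc`` draw densities on ``grid``."""
    spectra = model_spectra(model, theta, n, n_mc=n_mc, seed=seed, cache=cache)
    return mean_density([spectral_density(s, grid) for s in spectra])


def estimate_parameter(
    g: gm.Graph,
    model: GraphModelSpec,
    n_mc: int = 50,
    seed: int = 0,
    n_grid: int = 512,
    cache: Optional[dict] = None,
) -> EstimationResult:
    """Grid-search θ̂ = argmin_θ KL(ρ_G | ρ_M(θ)) at the graph's own size.

    The KL grid is shared: it spans the target spectrum and every
    Monte-Carlo spectrum across all candidate θ, padded by three
    bandwidths.  Ties break toward the earliest grid entry.
    """
    if g.n_vertices < 2:
        raise ValueError("graph must have at least 2 vertices")
    thetas = model.grid_for(g.n_vertices)
    if len(thetas) == 0:
        raise ValueError("empty parameter grid")
    n = g.n_vertices
    target = adjacency_spectrum(g)
    mc = {
        _theta_key(th): model_spectra(model, th, n, n_mc=n_mc, seed=seed, cache=cache)
        for th in thetas
    }
    all_spectra = [target]
    for sp in mc.values():
        all_spectra.extend(sp)
    grid = shared_grid(all_spectra, n_grid)
    p_target = grid_masses(spectral_density(target, grid))
    kl = np.empty(len(thetas))
    for idx, th in enumerate(thetas):
        rho_m = mean_density([spectral_density(s, grid) for s in mc[_theta_key(th)]])
        kl[idx] = kl_masses(p_target, grid_masses(rho_m))
    if not np.any(np.isfinite(kl)):
        raise EstimationFailedError("all grid points gave infinite KL")
    best = int(np.argmin(kl))
    return EstimationResult(
        theta_hat=thetas[best],
        kl_min=float(kl[best]),
        thetas=list(thetas),
        grid_kl=kl,
        n_mc=n_mc,
        size=n,
    )


def select_model(
    g: gm.Graph,
    candidates: Sequence[GraphModelSpec],
    n_mc: int = 50,
    seed: int = 0,
    n_grid: int = 512,
    cache: Optional[dict] = None,
) -> Tuple[str, EstimationResult]:
    """Pick the candidate family whose best-grid KL is smallest."""
    if len(candidates) == 0:
        raise ValueError("need at least one candidate model")
    best: Optional[Tuple[str, EstimationResult]] = None
    for cand in candidates:
        try:
            res = estimate_parameter(
                g, cand, n_mc=n_mc, seed=seed, n_grid=n_grid, cache=cache
            )
        except EstimationFailedError:
            continue
        if best is None or res.kl_min < best[1].kl_min:
            best = (cand.model_id, res)
    if best is None:
        raise EstimationFailedError("every candidate model failed to fit")
    return best
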
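"""Whole-graph clustering: JS k-means and the gCEM model-based algorithm.

Two complementary algorithms:

* :func:`kmeans_graphs` — k-means over spectral densities with the √JS
  metric.  Requires all graphs to share one vertex count (densities of
  different-size graphs have incomparable supports).  Assignment is an
  online greedy pass: each graph moves to its nearest centroid and both
  affected centroids are updated immediately, so the outcome depends on
  the (seed-controlled) visiting order.  Several random restarts are run
  and the result with the largest silhouette statistic is kept.

* :func:`gcem` — graph classification expectation-maximization for
  graphs of *different* sizes.  Each cluster is a random-graph model
  with parameter θ̂_k; the E-step scores each graph by the inverse KL
  divergence to each cluster's Monte-Carlo model density (generated at
  the graph's own size), the C-step assigns to the highest score, and
  the M-step re-estimates θ̂_k as the mean of the per-graph
  KL-minimizing estimates within the cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .divergence import grid_masses, js_masses, kl_masses
from .graph_models import Graph
from .param_estimation import (
    GraphModelSpec,
    estimate_parameter,
    model_spectra,
)
from .spectral import (
    SpectralDensity,
    adjacency_spectrum,
    mean_density,
    shared_grid,
    spectral_density,
)

__all__ = ["ClusteringResult", "kmeans_graphs", "silhouette", "gcem"]

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    """Labels plus per-cluster summaries and diagnostics.

    ``centroids`` holds per-cluster mean :class:`SpectralDensity` objects
    for k-means, or ``(model_id, theta_hat)`` pairs for gCEM.
    ``assignment_scores`` is the N×K matrix of √JS distances (k-means) or
    conditional probabilities t (gCEM, rows summing to 1).
    """

    labels: np.ndarray
    centroids: list
    assignment_scores: np.ndarray
    n_iterations: int
    converged: bool
    silhouette: Optional[float] = None
    objective_trace: Optional[List[float]] = None


def silhouette(labels: Sequence[int], pairwise_distances: np.ndarray) -> float:
    """Rousseeuw's mean silhouette from a precomputed distance matrix.

    Per item: (b − a) / max(a, b), with a the mean distance to the item's
    own cluster (excluding itself) and b the smallest mean distance to
    another cluster.  Singleton-cluster items contribute 0; a single
    cluster overall returns 0 by convention.
    """
    labels = np.asarray(labels)
    d = np.asarray(pairwise_distances, dtype=np.float64)
    n = labels.size
    if d.shape != (n, n):
        raise ValueError("distance matrix shape must match labels")
    clusters = np.unique(labels)
    if clusters.size < 2:
        return 0.0
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue  # singleton contributes 0
        a = d[i, own].sum() / (n_own - 1)
        b = math.inf
        for c in clusters:
            if c == labels[i]:
                continue
            b = min(b, d[i, labels == c].mean())
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def _masses_for_graphs(graphs: Sequence[Graph], n_grid: int):
    spectra = [adjacency_spectrum(g) for g in graphs]
    grid = shared_grid(spectra, n_grid)
    densities = [spectral_density(s, grid) for s in spectra]
    masses = np.stack([grid_masses(d) for d in densities])
    return grid, densities, masses


def _centroid(sums: np.ndarray, counts: np.ndarray, c: int) -> np.ndarray:
    # incremental +=/-= of masses can leave ~1e-20 negative dust, which
    # kl_masses would read as a support violation; clamp it away
    return np.maximum(sums[c], 0.0) / counts[c]


def _pairwise_sqrt_js(masses: np.ndarray) -> np.ndarray:
    n = masses.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = math.sqrt(js_masses(masses[i], masses[j]))
    return d


def _repair_empty(labels, sums, counts, masses, empty: int) -> int:
    """Move the graph farthest from its own centroid into ``empty``."""
    worst, worst_d = -1, -1.0
    for i in range(labels.size):
        c = labels[i]
        if counts[c] <= 1:
            continue
        dist = math.sqrt(js_masses(masses[i], _centroid(sums, counts, c)))
        if dist > worst_d:
            worst, worst_d = i, dist
    if worst < 0:  # every cluster is a singleton; give up quietly
        return -1
    c = labels[worst]
    sums[c] -= masses[worst]
    counts[c] -= 1
    sums[empty] += masses[worst]
    counts[empty] += 1
    labels[worst] = empty
    logger.warning("empty cluster %d repaired with graph %d", empty, worst)
    return worst


def _kmeans_single(masses: np.ndarray, k: int, rng, max_iter: int):
    n = masses.shape[0]
    labels = rng.integers(0, k, size=n)
    for c in range(k):  # guarantee nonempty initial clusters
        if not np.any(labels == c):
            donors = [i for i in range(n)
                      if np.sum(labels == labels[i]) > 1]
            labels[donors[int(rng.integers(len(donors)))]] = c
    sums = np.stack([masses[labels == c].sum(axis=0) for c in range(k)])
    counts = np.array([(labels == c).sum() for c in range(k)], dtype=np.int64)

    converged = False
    it = 0
    trace: List[float] = []
    for it in range(1, max_iter + 1):
        changed = 0
        for i in rng.permutation(n):
            dists = np.array(
                [math.sqrt(js_masses(masses[i], _centroid(sums, counts, c)))
                 for c in range(k)]
            )
            b = int(np.argmin(dists))  # ties -> lowest cluster index
            a = int(labels[i])
            if b == a:
                continue
            if counts[a] == 1:
                # moving the last member would empty cluster a; keep the
                # graph so every cluster stays populated and passes
                # terminate (repair handles degenerate initializations)
                continue
            sums[a] -= masses[i]
            counts[a] -= 1
            sums[b] += masses[i]
            counts[b] += 1
            labels[i] = b
            changed += 1
        objective = sum(
            math.sqrt(js_masses(masses[i], _centroid(sums, counts, labels[i])))
            for i in range(n)
        )
        trace.append(objective)
        logger.debug("k-means pass %d: %d moves, objective %.6f",
                     it, changed, objective)
        if changed == 0:
            converged = True
            break
    return labels, sums, counts, it, converged, trace


def kmeans_graphs(
    graphs: Sequence[Graph],
    k: int,
    n_restarts: int = 10,
    max_iter: int = 100,
    seed=None,
    n_grid: int = 512,
) -> ClusteringResult:
    """Cluster same-size graphs by k-means on spectral densities.

    Centroids are arithmetic means of the member densities; distances
    are √JS.  ``n_restarts`` independent random initializations are run
    and the restart with the largest silhouette (on the pairwise √JS
    matrix) is returned.
    """
    n = len(graphs)
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= {n} graphs, got k={k}")
    sizes = {g.n_vertices for g in graphs}
    if len(sizes) != 1:
        raise ValueError(
            f"k-means requires equal-size graphs (got sizes {sorted(sizes)}); "
            "use gcem for graphs of different sizes"
        )
    rng = np.random.default_rng(seed)
    grid, densities, masses = _masses_for_graphs(graphs, n_grid)
    pairwise = _pairwise_sqrt_js(masses) if k > 1 else None

    best = None
    for restart in range(n_restarts):
        labels, sums, counts, it, conv, trace = _kmeans_single(
            masses, k, rng, max_iter
        )
        sil = 0.0 if k == 1 else silhouette(labels, pairwise)
        logger.debug("restart %d: silhouette %.6f (%d passes)", restart, sil, it)
        if best is None or sil > best[0]:
            best = (sil, labels.copy(), sums.copy(), counts.copy(), it, conv, trace)

    sil, labels, sums, counts, it, conv, trace = best
    centroids = [
        mean_density([densities[i] for i in np.flatnonzero(labels == c)])
        for c in range(k)
    ]
    scores = np.array(
        [[math.sqrt(js_masses(masses[i], _centroid(sums, counts, c)))
          for c in range(k)]
         for i in range(n)]
    )
    return ClusteringResult(
        labels=labels,
        centroids=centroids,
        assignment_scores=scores,
        n_iterations=it,
        converged=conv,
        silhouette=sil,
        objective_trace=trace,
    )


def gcem(
    graphs: Sequence[Graph],
    k: int,
    models: Union[GraphModelSpec, Sequence[GraphModelSpec]],
    n_mc: int = 50,
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int = 0,
    n_grid: int = 512,
) -> ClusteringResult:
    """Model-based clustering of graphs that may differ in size.

    ``models`` is either one :class:`GraphModelSpec` shared by all
    clusters or a list of length ``k``.  Initialization partitions the
    graphs at random and runs one M-step.  Convergence is declared when
    the objective Σ_i t_{k(i)}(G_i)·KL_i changes by less than ``tol``
    relatively, or when labels are unchanged on two consecutive
    iterations, whichever happens first.

    Per-graph KL-minimizing estimates do not depend on the cluster
    parameters, so they are computed once per (graph, model family) and
    the M-step reduces to averaging them over cluster members.
    """
    n = len(graphs)
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= {n} graphs, got k={k}")
    if isinstance(models, GraphModelSpec):
        models = [models] * k
    models = list(models)
    if len(models) == 1:
        models = models * k
    if len(models) != k:
        raise ValueError(f"need 1 or {k} model specs, got {len(models)}")
    seed = 0 if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    cache: dict = {}

    spectra = [adjacency_spectrum(g) for g in graphs]
    graph_masses: dict = {}  # (i, grid key) -> masses; grids differ per pair

    est_cache: dict = {}

    def graph_estimate(i: int, cluster: int):
        key = (i, models[cluster].cache_key(), tuple(models[cluster].grid or ()))
        if key not in est_cache:
            est_cache[key] = np.asarray(
                np.atleast_1d(
                    estimate_parameter(
                        graphs[i], models[cluster], n_mc=n_mc, seed=seed,
                        n_grid=n_grid, cache=cache,
                    ).theta_hat
                ),
                dtype=np.float64,
            )
        return est_cache[key]

    def m_step(labels):
        thetas = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            est = np.mean([graph_estimate(i, c) for i in members], axis=0)
            thetas.append(est)
        return thetas

    def kl_to_model(i: int, cluster: int, theta) -> float:
        m = models[cluster]
        proj = m.project(theta, graphs[i].n_vertices)
        sp = model_spectra(m, proj, graphs[i].n_vertices, n_mc=n_mc,
                           seed=seed, cache=cache)
        grid = shared_grid([spectra[i]] + sp, n_grid)
        gkey = (i, round(float(grid[0]), 12), round(float(grid[-1]), 12), grid.size)
        if gkey not in graph_masses:
            graph_masses[gkey] = grid_masses(spectral_density(spectra[i], grid))
        rho_m = mean_density([spectral_density(s, grid) for s in sp])
        return kl_masses(graph_masses[gkey], grid_masses(rho_m))

    # -- initialization: random partition, one M-step
    labels = rng.integers(0, k, size=n)
    for c in range(k):
        if not np.any(labels == c):
            donors = [i for i in range(n) if np.sum(labels == labels[i]) > 1]
            labels[donors[int(rng.integers(len(donors)))]] = c
    thetas = m_step(labels)

    t = np.full((n, k), 1.0 / k)
    prev_objective = None
    prev_labels = labels.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: t_k(G_i) proportional to 1 / KL(rho_Gi | rho_Mk(theta_k))
        kl = np.array([[kl_to_model(i, c, thetas[c]) for c in range(k)]
                       for i in range(n)])
        t = np.zeros((n, k))
        for i in range(n):
            row = kl[i]
            if np.any(row == 0.0):
                t[i, row == 0.0] = 1.0 / np.sum(row == 0.0)
            elif not np.any(np.isfinite(row)):
                logger.warning("graph %d: infinite KL to every model; "
                               "uniform responsibilities", i)
                t[i] = 1.0 / k
            else:
                inv = np.where(np.isfinite(row), 1.0 / row, 0.0)
                t[i] = inv / inv.sum()
        # C-step: argmax responsibility, ties toward the lowest index
        new_labels = np.argmax(t, axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                candidates = [i for i in range(n)
                              if np.sum(new_labels == new_labels[i]) > 1]
                worst = min(candidates, key=lambda i: t[i].max())
                new_labels[worst] = c
                logger.warning("gcem: empty cluster %d repaired with graph %d",
                               c, worst)
        labels = new_labels
        # M-step
        thetas = m_step(labels)
        finite = np.isfinite(kl[np.arange(n), labels])
        objective = float(
            np.sum(t[np.arange(n), labels][finite] * kl[np.arange(n), labels][finite])
        )
        logger.debug("gcem iteration %d: objective %.6f", it, objective)
        labels_stable = np.array_equal(labels, prev_labels)
        if prev_objective is not None:
            rel = abs(objective - prev_objective) / max(abs(prev_objective), 1e-12)
            if rel < tol or labels_stable:
                converged = True
                break
        prev_objective = objective
        prev_labels = labels.copy()

    centroids = []
    for c in range(k):
        th = thetas[c]
        centroids.append(
            (models[c].model_id, float(th[0]) if th.size == 1 else tuple(th))
        )
    return ClusteringResult(
        labels=np.asarray(labels),
        centroids=centroids,
        assignment_scores=t,
        n_iterations=it,
        converged=converged,
        silhouette=None,
    )
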
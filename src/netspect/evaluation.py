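"""Clustering evaluation and the three simulation studies.

The pair-counting Jaccard index compares a predicted partition with the
ground truth over all item pairs: J = n11 / (n11 + n10 + n01), where
n11 counts pairs co-clustered in both partitions and n10/n01 pairs
co-clustered in exactly one.  J = 1 means identical clusterings up to
label renaming; for the 10+10 two-cluster design used throughout the
simulations, labels that are correct only half the time give J ≈ 0.32,
which is therefore the chance floor to compare against.

Three simulation families exercise the clustering algorithms:

* sim1 (a–f): three same-size clusters per scenario, from one family
  with different parameters (a–e) or three different families (f);
  clustered with k-means.
* sim2 (a, b): two clusters of n=100 graphs with matched edge counts
  (and in (b) matched degree sequences), where a sweep parameter —
  Watts-Strogatz rewiring probability, or the number of degree-
  preserving edge swaps — gradually erases the difference between the
  clusters; clustered with k-means.
* sim3 (a–f): the sim1 scenarios with per-graph sizes drawn uniformly
  from [30, 120]; clustered with gCEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics.cluster import pair_confusion_matrix

from . import graph_models as gm
from .clustering import gcem, kmeans_graphs
from .param_estimation import GraphModelSpec

__all__ = [
    "jaccard_index",
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "SCENARIO_IDS",
]


def jaccard_index(labels_true: Sequence, labels_pred: Sequence) -> float:
    """Pair-counting Jaccard index between two partitions."""
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two items")
    c = pair_confusion_matrix(a, b)  # ordered-pair counts (each pair twice)
    n11, n10, n01 = c[1, 1], c[1, 0], c[0, 1]
    denom = n11 + n10 + n01
    if denom == 0:  # no pair co-clustered anywhere: partitions agree trivially
        return 1.0
    return float(n11 / denom)


# --- scenario definitions -------------------------------------------------
# (model_id, parameters) per cluster; sizes/sweeps are filled in at run time.

_SIM1_MODELS = {
    "a": [("erdos_renyi_gnp", {"p": 0.2}),
          ("erdos_renyi_gnp", {"p": 0.25}),
          ("erdos_renyi_gnp", {"p": 0.3})],
    "b": [("geometric", {"r": 0.15}),
          ("geometric", {"r": 0.25}),
          ("geometric", {"r": 0.35})],
    "c": [("k_regular", {"k": 2}),
          ("k_regular", {"k": 4}),
          ("k_regular", {"k": 6})],
    "d": [("watts_strogatz", {"k": 16, "p": 0.05}),
          ("watts_strogatz", {"k": 16, "p": 0.10}),
          ("watts_strogatz", {"k": 16, "p": 0.15})],
    "e": [("preferential_attachment", {"m": 10, "ps": 1.0}),
          ("preferential_attachment", {"m": 10, "ps": 2.0}),
          ("preferential_attachment", {"m": 10, "ps": 3.0})],
    "f": [("geometric", {"r": 0.1}),
          ("preferential_attachment", {"m": 10, "ps": 1.5}),
          ("k_regular", {"k": 2})],
}

SCENARIO_IDS = tuple(
    [f"sim1{s}" for s in "abcdef"] + ["sim2a", "sim2b"]
    + [f"sim3{s}" for s in "abcdef"]
)

_SAMPLERS = {
    "erdos_renyi_gnp": lambda n, rng, p: gm.erdos_renyi_gnp(n, p, rng),
    "geometric": lambda n, rng, r: gm.geometric_graph(n, r, rng),
    "k_regular": lambda n, rng, k: gm.k_regular(n, k, rng),
    "watts_strogatz": lambda n, rng, k, p: gm.watts_strogatz(n, k, p, rng),
    "preferential_attachment":
        lambda n, rng, m, ps: gm.preferential_attachment(n, m, ps, rng),
}

# free parameter + estimation setup for gCEM in sim3
_SIM3_SPECS = {
    "erdos_renyi_gnp": lambda params: GraphModelSpec("erdos_renyi_gnp"),
    "geometric": lambda params: GraphModelSpec("geometric"),
    "k_regular": lambda params: GraphModelSpec("k_regular"),
    "watts_strogatz": lambda params: GraphModelSpec(
        "watts_strogatz", fixed={"k": params["k"]}
    ),
    "preferential_attachment": lambda params: GraphModelSpec(
        "preferential_attachment", fixed={"m": params["m"]}
    ),
}


@dataclass
class ScenarioConfig:
    """Configuration of one simulation scenario.

    ``n_vertices`` is a fixed size (sim1/sim2, default 100) or a
    ``(low, high)`` size range (sim3, default (30, 120)).
    ``sweep_value`` is the Watts–Strogatz rewiring probability (sim2a)
    or the number of edge swaps (sim2b).  ``model_grids`` optionally
    overrides the gCEM estimation grid per cluster (sim3).
    """

    scenario_id: str
    n_vertices: object = None
    graphs_per_cluster: int = 10
    sweep_value: object = None
    n_repetitions: int = 20
    seed: int = 0
    n_restarts: int = 10
    n_mc: int = 50
    max_iter: int = 50
    model_grids: Optional[Sequence] = None
    n_grid: int = 512

    def __post_init__(self):
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(
                f"unknown scenario {self.scenario_id!r}; choose from {SCENARIO_IDS}"
            )
        if self.n_vertices is None:
            self.n_vertices = (30, 120) if self.scenario_id.startswith("sim3") else 100
        if self.scenario_id.startswith("sim2") and self.sweep_value is None:
            self.sweep_value = 0


@dataclass
class ScenarioResult:
    """Per-repetition Jaccard indices with mean and normal-theory 95% CI."""

    jaccards: np.ndarray
    mean: float
    ci_half_width: float
    config: ScenarioConfig = field(repr=False, default=None)


def _draw_size(n_vertices, rng) -> int:
    if isinstance(n_vertices, (tuple, list)):
        lo, hi = n_vertices
        return int(rng.integers(lo, hi + 1))
    return int(n_vertices)


def _generate_sim1(config: ScenarioConfig, rng):
    scen = config.scenario_id[-1]
    graphs, truth = [], []
    for label, (model_id, params) in enumerate(_SIM1_MODELS[scen]):
        for _ in range(config.graphs_per_cluster):
            n = _draw_size(config.n_vertices, rng)
            graphs.append(_SAMPLERS[model_id](n, rng, **params))
            truth.append(label)
    return graphs, np.array(truth)


def _generate_sim2(config: ScenarioConfig, rng):
    n = int(config.n_vertices)
    gpc = config.graphs_per_cluster
    graphs, truth = [], []
    if config.scenario_id == "sim2a":
        p = float(config.sweep_value)
        for _ in range(gpc):
            graphs.append(gm.watts_strogatz(n, 20, p, rng))
            truth.append(0)
        for _ in range(gpc):
            graphs.append(gm.erdos_renyi_gnm(n, 1000, rng))
            truth.append(1)
    else:  # sim2b
        swaps = int(config.sweep_value)
        for _ in range(gpc):
            g = gm.watts_strogatz(n, 20, 0.0, rng)
            if swaps > 0:
                g = gm.markov_rewire(g, swaps, rng)
            graphs.append(g)
            truth.append(0)
        for _ in range(gpc):
            graphs.append(gm.k_regular(n, 20, rng))
            truth.append(1)
    return graphs, np.array(truth)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run a scenario ``n_repetitions`` times and collect Jaccard indices.

    sim1/sim2 repetitions generate fresh graphs and cluster them with
    k-means (K = number of generating models); sim3 repetitions use gCEM
    with the scenario's model families and each graph's own size.
    """
    sid = config.scenario_id
    rng = np.random.default_rng(config.seed)
    jaccards = np.empty(config.n_repetitions)
    for rep in range(config.n_repetitions):
        rep_seed = int(rng.integers(2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        if sid.startswith("sim1") or sid.startswith("sim3"):
            graphs, truth = _generate_sim1(config, rep_rng)
        else:
            graphs, truth = _generate_sim2(config, rep_rng)
        k = int(truth.max()) + 1
        if sid.startswith("sim3"):
            scen = sid[-1]
            models = []
            for idx, (model_id, params) in enumerate(_SIM1_MODELS[scen]):
                spec = _SIM3_SPECS[model_id](params)
                if config.model_grids is not None:
                    spec.grid = list(config.model_grids[idx]) if not isinstance(
                        config.model_grids, dict
                    ) else list(config.model_grids.get(idx, spec.grid or []))
                models.append(spec)
            result = gcem(
                graphs, k, models, n_mc=config.n_mc, max_iter=config.max_iter,
                seed=rep_seed, n_grid=config.n_grid,
            )
        else:
            result = kmeans_graphs(
                graphs, k, n_restarts=config.n_restarts, seed=rep_seed,
                n_grid=config.n_grid,
            )
        jaccards[rep] = jaccard_index(truth, result.labels)
    mean = float(jaccards.mean())
    se = float(jaccards.std(ddof=1) / np.sqrt(len(jaccards))) if len(jaccards) > 1 else 0.0
    return ScenarioResult(jaccards, mean, 1.96 * se, config)
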
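"""Graph and result readers/writers.

Graphs are exchanged as whitespace-separated edge lists (two integer
columns, ``#`` comments, 0-based ids by default), dense adjacency
matrices (CSV or whitespace), GraphML, or MatrixMarket adjacency.
Results are written as a JSON metadata document plus CSV tables so runs
are inspectable and re-readable without the library.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .clustering import ClusteringResult
from .evaluation import ScenarioResult
from .graph_models import Graph
from .param_estimation import EstimationResult
from .spectral import SpectralDensity

__all__ = ["read_graph", "write_graph", "write_result", "read_signals"]

SCHEMA_VERSION = 1


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".mtx":
        return "mtx"
    return "edgelist"


def read_graph(
    path,
    format: Optional[str] = None,
    n_vertices: Optional[int] = None,
    one_based: bool = False,
) -> Graph:
    """Read a graph file; format inferred from the extension unless given.

    Adjacency input is symmetrized (max of A and Aᵀ); self-loops are
    dropped with a warning.  ``one_based`` shifts edge-list ids down by
    one on input.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edgelist":
        return _read_edgelist(path, n_vertices, one_based)
    if fmt == "adjacency":
        text = path.read_text()
        delimiter = "," if "," in text.splitlines()[0] else None
        a = np.loadtxt(path, delimiter=delimiter)
        return _graph_from_adjacency(np.atleast_2d(a))
    if fmt == "mtx":
        a = scipy.io.mmread(path)
        if scipy.sparse.issparse(a):
            a = a.toarray()
        return _graph_from_adjacency(np.asarray(a))
    if fmt == "graphml":
        return Graph.from_networkx(nx.read_graphml(path))
    raise ValueError(f"unknown graph format {fmt!r}")


_NV_RE = re.compile(r"n_vertices\s*=\s*(\d+)")


def _read_edgelist(path: Path, n_vertices, one_based: bool) -> Graph:
    edges = []
    max_id = -1
    shift = 1 if one_based else 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text, _, comment = line.partition("#")
            if n_vertices is None and (match := _NV_RE.search(comment)):
                n_vertices = int(match.group(1))
            text = text.strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two ids, got {text!r}")
            try:
                i, j = int(parts[0]) - shift, int(parts[1]) - shift
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer id in {text!r}") from exc
            if i == j:
                warnings.warn(f"{path}:{lineno}: dropping self-loop at {i}")
                continue
            edges.append((i, j))
            max_id = max(max_id, i, j)
    n = n_vertices if n_vertices is not None else max_id + 1
    return Graph.from_edges(max(n, 1), edges)


def _graph_from_adjacency(a: np.ndarray) -> Graph:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got {a.shape}")
    if np.any(np.diag(a) != 0):
        warnings.warn("dropping self-loops from adjacency diagonal")
        a = a.copy()
        np.fill_diagonal(a, 0)
    return Graph.from_adjacency(a, symmetrize=True)


def write_graph(g: Graph, path, one_based: bool = False) -> None:
    """Write an edge list (two tab-separated integer columns)."""
    shift = 1 if one_based else 0
    with open(path, "w") as fh:
        fh.write(f"# netspect edge list; n_vertices={g.n_vertices}\n")
        for i, j in sorted(g.edges):
            fh.write(f"{i + shift}\t{j + shift}\n")


def read_signals(path, delimiter: Optional[str] = None) -> np.ndarray:
    """Read a channels × samples numeric table (CSV/TSV, channels as rows)."""
    df = pd.read_csv(path, sep=delimiter, header=None, engine="python")
    return df.to_numpy(dtype=np.float64)


def _meta(seed=None, **extra) -> dict:
    from . import __version__

    meta = {"schema_version": SCHEMA_VERSION, "library_version": __version__}
    if seed is not None:
        meta["seed"] = seed
    meta.update(extra)
    return meta


def write_result(result, path, seed=None) -> None:
    """Write a result object as ``<path>.json`` (+ ``<path>.csv`` table).

    Accepts :class:`ClusteringResult`, :class:`EstimationResult`, or
    :class:`ScenarioResult`.
    """
    path = Path(path)
    stem = path.with_suffix("") if path.suffix == ".json" else path
    if isinstance(result, ClusteringResult):
        table = pd.DataFrame(
            result.assignment_scores,
            columns=[f"score_{c}" for c in range(result.assignment_scores.shape[1])],
        )
        table.insert(0, "label", result.labels)
        table.insert(0, "graph", np.arange(len(result.labels)))
        meta = _meta(
            seed,
            kind="clustering",
            n_iterations=result.n_iterations,
            converged=bool(result.converged),
            silhouette=result.silhouette,
            centroids=[
                c if not isinstance(c, SpectralDensity) else "spectral_density"
                for c in result.centroids
            ],
        )
    elif isinstance(result, EstimationResult):
        table = pd.DataFrame({"theta": [str(t) for t in result.thetas],
                              "kl": result.grid_kl})
        meta = _meta(
            seed,
            kind="estimation",
            theta_hat=result.theta_hat,
            kl_min=result.kl_min,
            n_mc=result.n_mc,
            size=result.size,
        )
    elif isinstance(result, ScenarioResult):
        table = pd.DataFrame({
            "repetition": np.arange(len(result.jaccards)),
            "jaccard": result.jaccards,
        })
        meta = _meta(
            seed,
            kind="scenario",
            scenario_id=result.config.scenario_id if result.config else None,
            mean_jaccard=result.mean,
            ci_half_width=result.ci_half_width,
        )
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    table.to_csv(stem.with_suffix(".csv"), index=False)
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
        fh.write("\n")


def read_labels(path) -> np.ndarray:
    """Read the ``label`` column back from a clustering CSV."""
    return pd.read_csv(path)["label"].to_numpy()
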
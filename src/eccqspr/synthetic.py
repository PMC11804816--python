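"""Synthetic inputs and brute-force oracles.

Two generators make every pipeline stage testable without external data:

* :func:`random_molecular_graph` draws connected chemical-like graphs —
  a random spanning tree grown by uniform attachment under a degree cap
  (default 4, mimicking carbon valence in a hydrogen-suppressed skeleton),
  plus a requested number of ring-closing edges.
* :func:`random_regression_data` draws descriptor/property pairs
  y = alpha + beta*x + gamma*x^2 + N(0, sigma^2) with x uniform on a fixed
  interval, for regression parameter-recovery tests.

:func:`floyd_warshall_oracle` is a deliberately independent all-pairs
shortest-path implementation (dense O(n^3) relaxation, no code shared with
the BFS pipeline) used to cross-check distances, eccentricities and every
index derived from them.

Each operation derives its own named random stream from the single integer
seed in its spec; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import MolecularGraph

__all__ = [
    "GraphGenSpec",
    "RegressionGenSpec",
    "random_molecular_graph",
    "floyd_warshall_oracle",
    "oracle_eccentricities",
    "random_regression_data",
]

#: x values for synthetic regression data are uniform on this interval
X_RANGE = (0.0, 10.0)


def _stream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, int.from_bytes(label.encode(), "big")])


@dataclass(frozen=True)
class GraphGenSpec:
    """Recipe for one random chemical-like graph."""

    n: int
    rings: int = 0
    max_degree: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 3 <= self.n <= 60:
            raise ValueError(f"n must be in [3, 60], got {self.n}")
        if not 0 <= self.rings <= 5:
            raise ValueError(f"rings must be in [0, 5], got {self.rings}")
        if self.max_degree < 2:
            raise ValueError("max_degree must be >= 2")


@dataclass(frozen=True)
class RegressionGenSpec:
    """Recipe for one synthetic descriptor/property dataset."""

    n: int
    alpha: float
    beta: float
    gamma: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise ValueError(f"n must be >= 10, got {self.n}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def random_molecular_graph(spec: GraphGenSpec) -> MolecularGraph:
    """Connected simple graph with max degree <= cap; deterministic per seed.

    Vertices 1..n are joined into a random tree: vertex i attaches to a
    uniformly chosen earlier vertex that still has spare valence.  Then
    ``spec.rings`` extra edges are added between non-adjacent vertex pairs
    with spare valence, closing rings.  Raises if the requested rings cannot
    be placed under the cap.
    """
    rng = _stream(spec.seed, "graph")
    cap = spec.max_degree
    degree = {v: 0 for v in range(1, spec.n + 1)}
    edges: list[tuple[int, int]] = []
    for v in range(2, spec.n + 1):
        candidates = [u for u in range(1, v) if degree[u] < cap]
        if not candidates:
            raise ValueError(
                f"cannot grow a {spec.n}-vertex tree under degree cap {cap}")
        u = int(rng.choice(candidates))
        edges.append((u, v))
        degree[u] += 1
        degree[v] += 1
    present = {(min(u, v), max(u, v)) for u, v in edges}
    for _ in range(spec.rings):
        pool = [(u, v)
                for u in range(1, spec.n + 1) if degree[u] < cap
                for v in range(u + 1, spec.n + 1)
                if degree[v] < cap and (u, v) not in present]
        if not pool:
            raise ValueError(
                f"cannot place {spec.rings} ring edges on {spec.n} vertices "
                f"under degree cap {cap}")
        u, v = pool[int(rng.integers(len(pool)))]
        edges.append((u, v))
        present.add((u, v))
        degree[u] += 1
        degree[v] += 1
    return MolecularGraph(edges)


def floyd_warshall_oracle(g: MolecularGraph) -> np.ndarray:
    """All-pairs shortest-path matrix by dense Floyd-Warshall relaxation.

    Independent of the BFS route: operates on a dense adjacency matrix with
    the classic triple loop (vectorised over one axis).  Row/column order is
    ``g.vertices``.  Intended for small graphs (n <= ~60).
    """
    verts = g.vertices
    pos = {v: i for i, v in enumerate(verts)}
    n = len(verts)
    big = float(n + 1)  # exceeds any path length in a connected graph
    dist = np.full((n, n), big)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        dist[pos[u], pos[v]] = 1.0
        dist[pos[v], pos[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    if dist.max() >= big:
        raise ValueError("graph is disconnected")  # unreachable for MolecularGraph
    return dist.astype(int)


def oracle_eccentricities(g: MolecularGraph) -> dict[int, int]:
    """Eccentricities from the Floyd-Warshall oracle (for cross-checks)."""
    dist = floyd_warshall_oracle(g)
    return {v: int(dist[i].max()) for i, v in enumerate(g.vertices)}


def random_regression_data(spec: RegressionGenSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) with y = alpha + beta*x + gamma*x^2 + N(0, noise_sd^2)."""
    rng = _stream(spec.seed, "regression")
    x = rng.uniform(*X_RANGE, size=spec.n)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else 0.0
    y = spec.alpha + spec.beta * x + spec.gamma * x * x + noise
    return x, y
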
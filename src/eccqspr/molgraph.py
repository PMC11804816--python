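"""Hydrogen-suppressed molecular graphs and eccentricity machinery.

A molecule is modelled as its heavy-atom skeleton: vertices are non-hydrogen
atoms, edges are covalent bonds with bond order and aromaticity ignored.  All
distance-based descriptors in this package are built from the per-vertex
eccentricity

    xi(v) = max_u d(v, u),

the largest shortest-path distance from ``v`` to any other vertex, computed by
one breadth-first search per vertex.  The minimum and maximum eccentricities
are the graph's radius and diameter.

Graphs must be simple (no self-loops or parallel edges), undirected and
connected; a disconnected graph would make every eccentricity infinite and is
rejected outright rather than patched up.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "MolecularGraph",
    "GraphError",
    "EdgeListFormatError",
    "SelfLoopError",
    "DuplicateEdgeError",
    "DisconnectedGraphError",
    "SmilesBackendError",
    "read_edge_list",
    "read_smiles",
    "eccentricities",
    "vertex_ecc_partition",
    "edge_ecc_partition",
]


class GraphError(ValueError):
    """Base class for molecular-graph construction errors."""


class EdgeListFormatError(GraphError):
    """Malformed edge-list input (bad token, wrong field count)."""


class SelfLoopError(GraphError):
    """An edge joins a vertex to itself."""


class DuplicateEdgeError(GraphError):
    """The same unordered vertex pair appears twice."""


class DisconnectedGraphError(GraphError):
    """The graph is not connected, so eccentricities are undefined."""


class SmilesBackendError(GraphError):
    """No cheminformatics backend available to parse SMILES."""


@dataclass(frozen=True)
class MolecularGraph:
    """Simple connected undirected graph of heavy atoms.

    Parameters
    ----------
    edges
        Iterable of unordered vertex-id pairs (integers).
    elements
        Optional mapping vertex id -> element symbol; purely informational.

    The vertex set is exactly the set of ids appearing in ``edges`` (plus the
    single-vertex case is disallowed implicitly: a connected graph with at
    least one edge has >= 2 vertices).  Invariants — simplicity and
    connectedness — are enforced at construction.
    """

    edges: tuple[tuple[int, int], ...]
    elements: Mapping[int, str] | None = None
    _g: nx.Graph = field(init=False, repr=False, compare=False)

    def __init__(self, edges: Iterable[tuple[int, int]],
                 elements: Mapping[int, str] | None = None):
        seen: set[tuple[int, int]] = set()
        canon: list[tuple[int, int]] = []
        for u, v in edges:
            if u == v:
                raise SelfLoopError(f"self-loop at vertex {u}")
            e = (min(u, v), max(u, v))
            if e in seen:
                raise DuplicateEdgeError(f"duplicate edge {e}")
            seen.add(e)
            canon.append(e)
        g = nx.Graph(canon)
        if g.number_of_nodes() == 0:
            raise GraphError("graph has no edges")
        if not nx.is_connected(g):
            parts = [sorted(c) for c in nx.connected_components(g)]
            raise DisconnectedGraphError(
                f"graph is disconnected ({len(parts)} components: {parts})")
        if elements is not None:
            extra = set(elements) - set(g.nodes)
            if extra:
                raise GraphError(f"element labels for unknown vertices {sorted(extra)}")
        object.__setattr__(self, "edges", tuple(canon))
        object.__setattr__(self, "elements", dict(elements) if elements else None)
        object.__setattr__(self, "_g", g)

    # -- basic graph quantities -------------------------------------------

    @property
    def n(self) -> int:
        """Order |V(G)|: number of heavy atoms."""
        return self._g.number_of_nodes()

    @property
    def m(self) -> int:
        """Size |E(G)|: number of bonds."""
        return self._g.number_of_edges()

    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(sorted(self._g.nodes))

    def degree(self, v: int) -> int:
        return self._g.degree[v]

    def degrees(self) -> dict[int, int]:
        return {v: self._g.degree[v] for v in self.vertices}

    def neighbors(self, v: int) -> tuple[int, ...]:
        return tuple(sorted(self._g.neighbors(v)))

    def as_networkx(self) -> nx.Graph:
        """A copy of the underlying :class:`networkx.Graph`."""
        return self._g.copy()

    # -- distances ---------------------------------------------------------

    def distance_matrix(self) -> dict[int, dict[int, int]]:
        """All-pairs shortest-path lengths via one BFS per source vertex."""
        return {v: dict(nx.single_source_shortest_path_length(self._g, v))
                for v in self.vertices}

    def relabelled(self, mapping: Mapping[int, int]) -> "MolecularGraph":
        """The same graph with vertex ids renamed (for invariance testing)."""
        els = ({mapping[v]: s for v, s in self.elements.items()}
               if self.elements else None)
        return MolecularGraph([(mapping[u], mapping[v]) for u, v in self.edges], els)

    def summary(self) -> dict:
        """JSON-ready summary: order, size, radius, diameter, partitions."""
        ecc = eccentricities(self)
        return {
            "n": self.n,
            "m": self.m,
            "radius": min(ecc.values()),
            "diameter": max(ecc.values()),
            "vertex_partition": {str(k): c for k, c
                                 in sorted(vertex_ecc_partition(ecc).items())},
            "edge_partition": {f"{a},{b}": c for (a, b), c
                               in sorted(edge_ecc_partition(self, ecc).items())},
        }


# -- input formats ---------------------------------------------------------

def read_edge_list(path: str | Path) -> MolecularGraph:
    """Read a graph from a plain-text edge list.

    Format: one edge per line as two whitespace-separated positive integers
    (1-based vertex ids); blank lines and lines starting with ``#`` are
    ignored.  Malformed input raises a distinct diagnostic rather than being
    silently repaired.
    """
    edges: list[tuple[int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 2:
            raise EdgeListFormatError(
                f"{path}:{lineno}: expected two vertex ids, got {len(tokens)} tokens")
        try:
            u, v = int(tokens[0]), int(tokens[1])
        except ValueError:
            raise EdgeListFormatError(
                f"{path}:{lineno}: non-integer vertex token in {tokens!r}") from None
        edges.append((u, v))
    if not edges:
        raise EdgeListFormatError(f"{path}: no edges found")
    return MolecularGraph(edges)


def read_smiles(smiles: str) -> MolecularGraph:
    """Build the heavy-atom skeleton from a SMILES string.

    Requires RDKit.  Hydrogens are suppressed and every bond becomes a single
    edge regardless of order or aromaticity, so the result depends only on
    the molecule's connectivity.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - backend always in test env
        raise SmilesBackendError(
            "SMILES input requires rdkit; install the 'smiles' extra or "
            "supply an edge-list file instead") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumBonds() == 0:
        raise GraphError(f"SMILES {smiles!r} has fewer than two heavy atoms")
    elements = {a.GetIdx() + 1: a.GetSymbol() for a in mol.GetAtoms()}
    edges = [(b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1)
             for b in mol.GetBonds()]
    return MolecularGraph(edges, elements)


# -- eccentricities --------------------------------------------------------

def eccentricities(g: MolecularGraph) -> dict[int, int]:
    """Per-vertex eccentricity xi(v) = max_u d(v, u), by BFS from each vertex."""
    nxg = g.as_networkx()
    return {v: max(nx.single_source_shortest_path_length(nxg, v).values())
            for v in g.vertices}


def vertex_ecc_partition(ecc: Mapping[int, int]) -> dict[int, int]:
    """Count vertices by eccentricity value: {xi : #vertices with that xi}."""
    if not ecc:
        raise ValueError("empty eccentricity vector")
    return dict(Counter(ecc.values()))


def edge_ecc_partition(g: MolecularGraph,
                       ecc: Mapping[int, int]) -> dict[tuple[int, int], int]:
    """Count edges by unordered endpoint-eccentricity pair.

    Keys are stored as (min, max); every index below is symmetric in the two
    endpoint eccentricities, so the orientation carries no information.
    """
    pairs = Counter()
    for u, v in g.edges:
        a, b = ecc[u], ecc[v]
        pairs[(min(a, b), max(a, b))] += 1
    return dict(pairs)
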
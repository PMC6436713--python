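"""County adjacency structures for spatial smoothing.

The intrinsic CAR prior needs, for every county, the list of its neighbours.
We store the structure in the flattened neighbour-list form used by the BUGS
``car.normal`` distribution: a concatenated neighbour vector ``adj``, a
per-county neighbour count ``num`` and unit edge weights, which round-trips
losslessly through JSON and maps directly onto the graph Laplacian
``L = D - W`` used by the density and sampling code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay

__all__ = ["AdjacencyStructure", "generate_adjacency", "DisconnectedGraphError"]


class DisconnectedGraphError(ValueError):
    """Raised when an operation requires a connected adjacency graph."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        super().__init__(
            f"adjacency graph is disconnected; components: {self.components}"
        )


@dataclass
class AdjacencyStructure:
    """Flattened neighbour-list representation of a county adjacency graph.

    Attributes
    ----------
    adj : list[int]
        Concatenated neighbour indices (0-based), county by county.
    num : list[int]
        Number of neighbours of each county; ``sum(num) == len(adj)``.
    weights : list[float]
        Edge weights aligned with ``adj``; always 1 for the intrinsic CAR.
    county_ids : list
        Labels for the counties, defaulting to ``0..n-1``.
    """

    adj: list
    num: list
    weights: list = field(default=None)
    county_ids: list = field(default=None)

    def __post_init__(self):
        self.adj = [int(a) for a in self.adj]
        self.num = [int(m) for m in self.num]
        if self.weights is None:
            self.weights = [1.0] * len(self.adj)
        if self.county_ids is None:
            self.county_ids = list(range(len(self.num)))
        self.validate()

    # -- basic facts ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.num)

    @property
    def sum_num_neigh(self) -> int:
        return len(self.adj)

    def neighbors(self, j: int) -> list:
        start = int(np.sum(self.num[:j]))
        return self.adj[start : start + self.num[j]]

    def edges(self) -> list:
        """Unordered neighbour pairs, each counted once."""
        out = []
        pos = 0
        for j, m in enumerate(self.num):
            for i in self.adj[pos : pos + m]:
                if j < i:
                    out.append((j, i))
            pos += m
        return out

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        n = self.n
        if len(self.adj) != int(np.sum(self.num)):
            raise ValueError("len(adj) must equal sum(num)")
        if len(self.weights) != len(self.adj):
            raise ValueError("weights must align with adj")
        if any(a < 0 or a >= n for a in self.adj):
            raise ValueError("neighbour index out of range")
        nb = {j: set(self.neighbors(j)) for j in range(n)}
        for j in range(n):
            if j in nb[j]:
                raise ValueError(f"county {j} listed as its own neighbour")
            for i in nb[j]:
                if j not in nb[i]:
                    raise ValueError(f"asymmetric adjacency between {j} and {i}")

    # -- linear-algebra views -------------------------------------------
    def weight_matrix(self) -> sp.csr_matrix:
        rows, cols = [], []
        pos = 0
        for j, m in enumerate(self.num):
            for i in self.adj[pos : pos + m]:
                rows.append(j)
                cols.append(i)
            pos += m
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def laplacian(self) -> np.ndarray:
        W = self.weight_matrix().toarray()
        return np.diag(W.sum(axis=1)) - W

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    def connected_components(self) -> list:
        return [set(c) for c in nx.connected_components(self.to_graph())]

    def require_connected(self) -> None:
        comps = self.connected_components()
        if len(comps) > 1:
            raise DisconnectedGraphError(comps)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "adj": self.adj,
            "num": self.num,
            "weights": self.weights,
            "sumNumNeigh": self.sum_num_neigh,
            "county_ids": self.county_ids,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AdjacencyStructure":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            adj=d["adj"],
            num=d["num"],
            weights=d.get("weights"),
            county_ids=d.get("county_ids"),
        )

    @classmethod
    def from_graph(cls, g: nx.Graph, county_ids=None) -> "AdjacencyStructure":
        nodes = sorted(g.nodes())
        index = {v: k for k, v in enumerate(nodes)}
        adj, num = [], []
        for v in nodes:
            nbrs = sorted(index[w] for w in g.neighbors(v))
            adj.extend(nbrs)
            num.append(len(nbrs))
        return cls(adj=adj, num=num, county_ids=county_ids)


def _lattice_graph(n: int) -> nx.Graph:
    # nearest-to-square factorisation; primes degenerate to a path, which is
    # still a valid connected lattice
    r = max(d for d in range(1, int(np.sqrt(n)) + 1) if n % d == 0)
    c = n // r
    g = nx.grid_2d_graph(r, c)
    return nx.convert_node_labels_to_integers(g, ordering="sorted")


def _random_planar_graph(n: int, rng: np.random.Generator, max_attempts: int = 20) -> nx.Graph:
    """Delaunay triangulation of random points: planar and connected."""
    for _ in range(max_attempts):
        pts = rng.uniform(size=(n, 2))
        try:
            tri = Delaunay(pts)
        except Exception:  # degenerate point set; redraw
            continue
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for simplex in tri.simplices:
            for a in range(3):
                g.add_edge(int(simplex[a]), int(simplex[(a + 1) % 3]))
        if nx.is_connected(g):
            return g
    raise RuntimeError(f"could not generate a connected planar graph in {max_attempts} attempts")


def generate_adjacency(n_counties: int, kind: str = "lattice", seed: int = 0) -> AdjacencyStructure:
    """Generate a symmetric, self-loop-free, connected county adjacency.

    Parameters
    ----------
    n_counties : int
        Number of counties (>= 2).
    kind : {"lattice", "random-planar"}
        ``lattice`` builds a grid (near-square factorisation of ``n``);
        ``random-planar`` triangulates random points (Delaunay), giving an
        irregular planar graph like a real county map.
    seed : int
        Seed for the random-planar draw; ignored for lattices.
    """
    if n_counties < 2:
        raise ValueError(f"n_counties must be >= 2, got {n_counties}")
    if kind == "lattice":
        g = _lattice_graph(n_counties)
    elif kind == "random-planar":
        rng = np.random.default_rng(seed)
        g = _random_planar_graph(n_counties, rng)
    else:
        raise ValueError(f"unknown adjacency kind: {kind!r}")
    if n_counties == 2 and g.number_of_edges() == 0:  # cannot happen, guard anyway
        g.add_edge(0, 1)
    structure = AdjacencyStructure.from_graph(g)
    structure.require_connected()
    return structure
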
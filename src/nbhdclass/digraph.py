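"""Finite simple digraphs and vertex neighbourhoods.

A digraph here is a finite set of vertices ``0..n-1`` and a set of arcs
(ordered vertex pairs).  Reciprocal arcs are allowed; self-loops and
parallel arcs are not.  The adjacency matrix is stored as a sparse
boolean CSR matrix ``A`` with ``A[i, j] = 1`` iff the arc ``i -> j``
exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Digraph",
    "Neighbourhood",
    "DegreeProfile",
    "from_edge_list",
    "read_edge_list",
    "read_mtx",
    "closed_neighbourhood",
    "open_neighbourhood",
    "induced_subgraph",
    "degree_profile",
    "largest_scc",
    "permute_vertices",
]


class Digraph:
    """A finite simple directed graph with 0-based contiguous vertex ids."""

    __slots__ = ("adjacency", "_n")

    def __init__(self, adjacency: sp.spmatrix):
        adj = sp.csr_matrix(adjacency, dtype=bool)
        adj.eliminate_zeros()
        if adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if adj.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = adj
        self._n = adj.shape[0]

    @property
    def num_vertices(self) -> int:
        return self._n

    @property
    def num_arcs(self) -> int:
        return int(self.adjacency.nnz)

    def arcs(self) -> list[tuple[int, int]]:
        """All arcs as (source, target) pairs, lexicographically sorted."""
        coo = self.adjacency.tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def has_arc(self, u: int, v: int) -> bool:
        return bool(self.adjacency[u, v])

    def out_neighbours(self, v: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[v] : self.adjacency.indptr[v + 1]
        ]

    def in_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0)).ravel().astype(np.int64)

    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def dense(self) -> np.ndarray:
        return self.adjacency.toarray().astype(np.int64)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Digraph):
            return NotImplemented
        return self._n == other._n and (
            (self.adjacency != other.adjacency).nnz == 0
        )

    def __hash__(self):  # mutable sparse payload; identity hashing only
        return id(self)

    def __repr__(self) -> str:
        return f"Digraph(n={self._n}, arcs={self.num_arcs})"


@dataclass(frozen=True)
class Neighbourhood:
    """A closed (or open) neighbourhood realised as an induced subgraph.

    ``member_map[i]`` is the ambient vertex id of local vertex ``i``;
    ``centre`` is the ambient id of the central vertex (absent from the
    subgraph for open neighbourhoods).
    """

    centre: int
    subgraph: Digraph
    member_map: tuple[int, ...]

    @property
    def members(self) -> frozenset[int]:
        return frozenset(self.member_map)

    @property
    def local_centre(self) -> int | None:
        try:
            return self.member_map.index(self.centre)
        except ValueError:
            return None

    @property
    def size(self) -> int:
        return len(self.member_map)


@dataclass(frozen=True)
class DegreeProfile:
    """In/out/reciprocal arc counts at one vertex.

    ``ind = in_only + reciprocal`` and ``oud = out_only + reciprocal``;
    ``deg = ind + oud`` counts reciprocal neighbours twice.
    """

    in_only: int
    out_only: int
    reciprocal: int
    ind: int = field(init=False)
    oud: int = field(init=False)
    deg: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "ind", self.in_only + self.reciprocal)
        object.__setattr__(self, "oud", self.out_only + self.reciprocal)
        object.__setattr__(self, "deg", self.ind + self.oud)


def from_edge_list(pairs, num_vertices: int | None = None) -> Digraph:
    """Build a digraph from (source, target) pairs; duplicates are merged.

    ``num_vertices`` defaults to ``1 + max vertex id`` (0 for no arcs).
    """
    rows, cols = [], []
    for u, v in pairs:
        u, v = int(u), int(v)
        if u == v:
            raise ValueError(f"self-loop ({u}, {v}) is not allowed")
        if u < 0 or v < 0:
            raise ValueError(f"negative vertex id in arc ({u}, {v})")
        rows.append(u)
        cols.append(v)
    n_min = 1 + max(rows + cols) if rows else 0
    n = n_min if num_vertices is None else int(num_vertices)
    if n < n_min:
        raise ValueError(f"num_vertices={n} smaller than 1 + max id {n_min - 1}")
    data = np.ones(len(rows), dtype=bool)
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    adj.sum_duplicates()
    return Digraph(adj)


def read_edge_list(path) -> Digraph:
    """Read a TSV edge list ``src<TAB>dst``; lines starting with '#' ignored."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split()[:2]
            pairs.append((int(u), int(v)))
    return from_edge_list(pairs)


def read_mtx(path) -> Digraph:
    """Read a MatrixMarket coordinate (pattern/general) adjacency matrix."""
    import scipy.io as sio

    m = sio.mmread(path).tocsr()
    return Digraph(m.astype(bool))


def write_edge_list(g: Digraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# src\tdst\n")
        for u, v in g.arcs():
            fh.write(f"{u}\t{v}\n")


def _check_vertex(g: Digraph, v0: int) -> None:
    if not (0 <= v0 < g.num_vertices):
        raise ValueError(f"vertex {v0} out of range for graph on {g.num_vertices}")


def induced_subgraph(g: Digraph, members) -> Digraph:
    """Subgraph induced on ``members``; local ids follow ascending ambient id."""
    idx = np.asarray(sorted(set(int(m) for m in members)), dtype=np.int64)
    if idx.size and (idx[0] < 0 or idx[-1] >= g.num_vertices):
        raise ValueError("member vertex out of range")
    sub = g.adjacency[idx][:, idx] if idx.size else sp.csr_matrix((0, 0), dtype=bool)
    return Digraph(sub)


def _neighbour_ids(g: Digraph, v0: int) -> np.ndarray:
    out_n = g.out_neighbours(v0)
    in_n = g.adjacency.tocsc().indices[
        g.adjacency.tocsc().indptr[v0] : g.adjacency.tocsc().indptr[v0 + 1]
    ]
    return np.union1d(out_n, in_n)


def closed_neighbourhood(g: Digraph, v0: int) -> Neighbourhood:
    """Subgraph induced by ``v0`` and all vertices adjacent to it either way."""
    _check_vertex(g, v0)
    members = np.union1d(_neighbour_ids(g, v0), [v0])
    return Neighbourhood(
        centre=v0,
        subgraph=induced_subgraph(g, members),
        member_map=tuple(int(m) for m in members),
    )


def open_neighbourhood(g: Digraph, v0: int) -> Neighbourhood:
    """Subgraph induced by the neighbours of ``v0``, excluding ``v0`` itself."""
    _check_vertex(g, v0)
    members = _neighbour_ids(g, v0)
    return Neighbourhood(
        centre=v0,
        subgraph=induced_subgraph(g, members),
        member_map=tuple(int(m) for m in members),
    )


def degree_profile(g: Digraph, v0: int) -> DegreeProfile:
    _check_vertex(g, v0)
    out_set = set(g.out_neighbours(v0).tolist())
    csc = g.adjacency.tocsc()
    in_set = set(csc.indices[csc.indptr[v0] : csc.indptr[v0 + 1]].tolist())
    r = len(out_set & in_set)
    return DegreeProfile(
        in_only=len(in_set) - r, out_only=len(out_set) - r, reciprocal=r
    )


def largest_scc(g: Digraph) -> frozenset[int]:
    """Vertex set of a maximum strongly connected component.

    Ties between equal-sized components are broken towards the one
    containing the smallest vertex id.
    """
    if g.num_vertices == 0:
        return frozenset()
    n_comp, labels = connected_components(
        g.adjacency, directed=True, connection="strong"
    )
    sizes = np.bincount(labels, minlength=n_comp)
    best = sizes.max()
    # first vertex (smallest id) whose component has maximal size
    winner = labels[np.flatnonzero(sizes[labels] == best)[0]]
    return frozenset(np.flatnonzero(labels == winner).tolist())


def permute_vertices(g: Digraph, sigma) -> Digraph:
    """Relabel vertices: arc (u, v) maps to (sigma[u], sigma[v])."""
    sigma = np.asarray(sigma, dtype=np.int64)
    n = g.num_vertices
    if sigma.shape != (n,) or not np.array_equal(np.sort(sigma), np.arange(n)):
        raise ValueError("sigma must be a permutation of all vertex ids")
    coo = g.adjacency.tocoo()
    adj = sp.csr_matrix(
        (coo.data, (sigma[coo.row], sigma[coo.col])), shape=(n, n), dtype=bool
    )
    return Digraph(adj)
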
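"""Directed flag complexes, Euler characteristic and Betti numbers.

The directed flag complex of a digraph has as its n-simplices the
directed (n+1)-cliques: ordered vertex tuples (v0, ..., vn) with an arc
vi -> vj for every i < j.  Homology is computed over a prime field
(default GF(2)) or the rationals, by ranks of the simplicial boundary
maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .digraph import Digraph

__all__ = [
    "DirectedFlagComplex",
    "BettiVector",
    "build_complex",
    "euler_characteristic",
    "betti_numbers",
    "normalised_betti_coefficient",
]


@dataclass(frozen=True)
class DirectedFlagComplex:
    """Ordered simplices per dimension, built up to a dimension cap.

    ``truncated`` is True when simplices of dimension ``max_dim_computed``
    exist, so higher-dimensional simplices may have been cut off.
    """

    simplices_by_dim: tuple[tuple[tuple[int, ...], ...], ...]
    max_dim_computed: int

    @property
    def simplex_counts(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.simplices_by_dim)

    @property
    def dimension(self) -> int:
        return len(self.simplices_by_dim) - 1

    @property
    def truncated(self) -> bool:
        return (
            self.dimension == self.max_dim_computed
            and len(self.simplices_by_dim[-1]) > 0
            # a complex that genuinely ends exactly at the cap is only
            # potentially truncated; we flag it conservatively unless the
            # cap exceeds the realised dimension
        )


@dataclass(frozen=True)
class BettiVector:
    betti: tuple[int, ...]
    field_char: int
    simplex_counts: tuple[int, ...]
    truncated: bool = False


def build_complex(g: Digraph, max_dim: int = 3) -> DirectedFlagComplex:
    """Enumerate all directed cliques of dimension <= ``max_dim``.

    Extension proceeds over the intersection of the out-neighbourhoods of
    the current tuple, so every stored tuple (v0, ..., vk) carries an arc
    vi -> vj for all i < j.  Tuples are listed in lexicographic order.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    n = g.num_vertices
    by_dim: list[list[tuple[int, ...]]] = [[(v,) for v in range(n)]]
    if max_dim == 0 or n == 0:
        return DirectedFlagComplex(
            tuple(tuple(d) for d in by_dim), max_dim_computed=max_dim
        )
    out_sets = [frozenset(g.out_neighbours(v).tolist()) for v in range(n)]
    frontier = sorted(g.arcs())
    if not frontier:
        return DirectedFlagComplex(
            tuple(tuple(d) for d in by_dim), max_dim_computed=max_dim
        )
    by_dim.append(list(frontier))
    dim = 1
    # carry the running out-intersection alongside each tuple
    carry = [((u, v), out_sets[u] & out_sets[v]) for u, v in frontier]
    while dim < max_dim and carry:
        nxt = []
        for simplex, common in carry:
            for w in sorted(common):
                nxt.append((simplex + (w,), common & out_sets[w]))
        if not nxt:
            break
        nxt.sort(key=lambda t: t[0])
        by_dim.append([t[0] for t in nxt])
        carry = nxt
        dim += 1
    # drop trailing empty dimension lists (none created by construction)
    return DirectedFlagComplex(
        tuple(tuple(d) for d in by_dim), max_dim_computed=max_dim
    )


def euler_characteristic(c: DirectedFlagComplex) -> int:
    """Alternating sum of simplex counts over all computed dimensions."""
    return int(sum((-1) ** i * s for i, s in enumerate(c.simplex_counts)))


def _boundary_columns(c: DirectedFlagComplex, n: int) -> list[list[tuple[int, int]]]:
    """Columns of the boundary map ∂_n as (row index, sign) pairs.

    Row indices refer to the lexicographic position of each (n-1)-face.
    """
    faces = {s: i for i, s in enumerate(c.simplices_by_dim[n - 1])}
    cols = []
    for simplex in c.simplices_by_dim[n]:
        col = []
        for i in range(len(simplex)):
            face = simplex[:i] + simplex[i + 1 :]
            col.append((faces[face], -1 if i % 2 else 1))
        cols.append(col)
    return cols


def _rank_gf(cols: list[list[tuple[int, int]]], nrows: int, p: int) -> int:
    """Rank over GF(p) by sparse column elimination."""
    pivots: dict[int, dict[int, int]] = {}  # pivot row -> column dict
    rank = 0
    for col in cols:
        vec = {r: s % p for r, s in col if s % p}
        while vec:
            piv = max(vec)
            if piv not in pivots:
                inv = pow(vec[piv], p - 2, p) if p > 2 else 1
                pivots[piv] = {r: (v * inv) % p for r, v in vec.items()}
                rank += 1
                break
            coef = vec[piv]
            other = pivots[piv]
            for r, v in other.items():
                nv = (vec.get(r, 0) - coef * v) % p
                if nv:
                    vec[r] = nv
                else:
                    vec.pop(r, None)
        # empty vec: column dependent
    return rank


def _rank_rational(cols, nrows: int, ncols: int) -> int:
    if ncols == 0 or nrows == 0:
        return 0
    m = np.zeros((nrows, ncols))
    for j, col in enumerate(cols):
        for r, s in col:
            m[r, j] = s
    return int(np.linalg.matrix_rank(m))


def betti_numbers(
    c: DirectedFlagComplex, field_char: int = 2
) -> BettiVector:
    """Betti numbers β_i = s_i − rank ∂_i − rank ∂_{i+1} over the field.

    ``field_char`` is a prime (modular arithmetic) or 0 (rationals).
    """
    if field_char != 0 and (
        field_char < 2 or any(field_char % q == 0 for q in range(2, field_char))
    ):
        raise ValueError(f"field characteristic must be 0 or prime, got {field_char}")
    counts = c.simplex_counts
    top = len(counts) - 1
    ranks = [0] * (top + 2)  # ranks[i] = rank ∂_i, ∂_0 = 0
    for i in range(1, top + 1):
        cols = _boundary_columns(c, i)
        if field_char == 0:
            ranks[i] = _rank_rational(cols, counts[i - 1], counts[i])
        else:
            ranks[i] = _rank_gf(cols, counts[i - 1], field_char)
    betti = tuple(
        counts[i] - ranks[i] - ranks[i + 1] for i in range(top + 1)
    )
    return BettiVector(
        betti=betti,
        field_char=field_char,
        simplex_counts=counts,
        truncated=c.truncated,
    )


def normalised_betti_coefficient(b: BettiVector) -> float:
    """Sum of (i+1) · β_i / s_i over dimensions with s_i > 0.

    Weights homology by simplex counts per dimension, giving higher
    dimensions increasing weight; dimensions with no simplices contribute
    nothing (β_i is necessarily 0 there).
    """
    total = 0.0
    for i, (beta, s) in enumerate(zip(b.betti, b.simplex_counts)):
        if s > 0:
            total += (i + 1) * beta / s
    return total


def write_simplex_counts(c: DirectedFlagComplex, path) -> None:
    """Dump per-dimension simplex counts as TSV for cross-checking
    against external flag-complex tools."""
    with open(path, "w") as fh:
        fh.write("dim\tcount\n")
        for dim, count in enumerate(c.simplex_counts):
            fh.write(f"{dim}\t{count}\n")
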
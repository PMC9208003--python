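"""Selection and feature parameters for digraphs.

Every parameter is a real-valued digraph invariant, addressable by a
short code.  Codes follow the field's abbreviations:

===========  ====================================================
``fcc``      Fagiolo clustering coefficient (at the centre)
``tcc``      transitive clustering coefficient (at the centre)
``ec``       Euler characteristic of the directed flag complex
``nbc``      normalised Betti coefficient
``size``     vertex count
``asg/asr``  adjacency spectral gap / radius
``tpsg/tpsr``  transition probability spectral gap / radius
``blsg/blsr``  Bauer Laplacian spectral gap / radius
``clsg/clsr``  Chung Laplacian spectral gap / radius
``deg/ind/oud``  total / in / out degree of the centre
===========  ====================================================

Spectral gaps default to the "high" convention (difference of the two
largest eigenvalue moduli) except for the Chung Laplacian, whose gap is
the smallest nonzero eigenvalue ("low").  Suffixes ``_high`` / ``_low``
override the convention and ``_rev`` swaps in- for out-degrees in the
transition and Bauer matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .digraph import Digraph, degree_profile, induced_subgraph, largest_scc
from .flag import betti_numbers, build_complex, euler_characteristic, \
    normalised_betti_coefficient

__all__ = [
    "PARAMETER_CODES",
    "SpectrumSummary",
    "fagiolo_cc",
    "transitive_3clique_count",
    "transitive_cc",
    "size_param",
    "transition_matrix",
    "bauer_laplacian",
    "chung_laplacian",
    "chung_spectral_gap",
    "spectrum_summary",
    "evaluate_parameter",
]

_TOL = 1e-9


@dataclass(frozen=True)
class SpectrumSummary:
    """Eigenvalue moduli of a matrix, with the derived gap statistics."""

    moduli: tuple[float, ...]  # sorted descending, with multiplicity
    radius: float
    gap_high: float  # difference of the two largest moduli
    gap_low: float  # smallest modulus exceeding the tolerance, else 0


def spectrum_summary(m: np.ndarray, tolerance: float = _TOL) -> SpectrumSummary:
    m = np.asarray(m, dtype=float)
    if m.size == 0:
        return SpectrumSummary(moduli=(), radius=0.0, gap_high=0.0, gap_low=0.0)
    moduli = np.sort(np.abs(np.linalg.eigvals(m)))[::-1]
    radius = float(moduli[0])
    gap_high = float(moduli[0] - moduli[1]) if moduli.size > 1 else 0.0
    floor = max(tolerance * radius, 1e-12)
    nonzero = moduli[moduli > floor]
    gap_low = float(nonzero[-1]) if nonzero.size else 0.0
    return SpectrumSummary(
        moduli=tuple(float(x) for x in moduli),
        radius=radius,
        gap_high=gap_high,
        gap_low=gap_low,
    )


def fagiolo_cc(g: Digraph, v0: int) -> float:
    """Fagiolo's directed clustering coefficient at ``v0``.

    Counts equivalence classes of directed triangles at the vertex
    (cyclic ones merged in pairs) against the count attainable on a
    complete reciprocal neighbourhood; 0 when no triangle can exist.
    """
    prof = degree_profile(g, v0)
    denom = prof.deg * (prof.deg - 1) - 2 * prof.reciprocal
    if denom <= 0:
        return 0.0
    a = g.dense().astype(float)
    s = a + a.T
    t = float((s[v0] @ s @ s[:, v0])) / 2.0
    return t / denom


def transitive_3clique_count(g: Digraph, v0: int) -> int:
    """Number of directed 3-cliques (transitive tournaments) containing v0.

    Each directed 3-clique is an ordered triple (a, b, c) with arcs
    a->b, a->c, b->c; a triple of vertices with reciprocal connections
    supports several and each is counted once.
    """
    a = g.dense().astype(np.int64)
    r = a[v0]  # out-indicator row
    c = a[:, v0]  # in-indicator column
    ar = a @ r
    return int(r @ ar + c @ ar + c @ (a @ c))


def transitive_cc(g: Digraph, v0: int) -> float:
    """Transitive clustering coefficient: directed 3-cliques at ``v0``
    divided by the maximum number realisable given its degree profile,
    ``deg(deg-1) - ind*oud - R``."""
    prof = degree_profile(g, v0)
    denom = prof.deg * (prof.deg - 1) - prof.ind * prof.oud - prof.reciprocal
    if denom <= 0:
        return 0.0
    return transitive_3clique_count(g, v0) / denom


def size_param(g: Digraph) -> int:
    return g.num_vertices


def transition_matrix(g: Digraph, reversed: bool = False) -> np.ndarray:
    """Row-stochastic matrix D_out^-1 A (rows of sinks left all-zero);
    the reversed variant normalises by in-degree instead."""
    a = g.dense().astype(float)
    d = g.in_degrees() if reversed else g.out_degrees()
    inv = np.divide(1.0, d, out=np.zeros(len(d)), where=d > 0)
    return inv[:, None] * a


def bauer_laplacian(g: Digraph, reversed: bool = False) -> np.ndarray:
    """I - D_in^-1 A with the whole row zeroed where ind = 0.

    Defined for any digraph (no strong-connectivity requirement); the
    spectrum is complex in general.  The reversed variant uses
    out-degrees.
    """
    a = g.dense().astype(float)
    d = g.out_degrees() if reversed else g.in_degrees()
    n = g.num_vertices
    inv = np.divide(1.0, d, out=np.zeros(n), where=d > 0)
    lap = np.eye(n) - inv[:, None] * a
    lap[d == 0, :] = 0.0
    return lap


def _perron_vector(p: np.ndarray) -> np.ndarray:
    """Left Perron vector phi of a row-stochastic irreducible matrix,
    normalised to sum 1 (the stationary distribution, phi P = phi)."""
    vals, vecs = np.linalg.eig(p.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    phi = np.real(vecs[:, k])
    phi = phi / phi.sum()
    if np.any(phi <= 0):
        # power-iteration fallback on a damped chain
        n = p.shape[0]
        phi = np.full(n, 1.0 / n)
        q = 0.99 * p + 0.01 * np.full((n, n), 1.0 / n)
        for _ in range(10000):
            nxt = phi @ q
            if np.max(np.abs(nxt - phi)) < 1e-14:
                phi = nxt
                break
            phi = nxt
        phi = phi / phi.sum()
    if np.any(phi <= 0):
        raise ValueError("failed to obtain a positive Perron vector")
    return phi


def chung_laplacian(g: Digraph) -> np.ndarray:
    """Symmetric directed-graph Laplacian of Chung.

    L = I - (Phi^1/2 P Phi^-1/2 + Phi^-1/2 P* Phi^1/2) / 2 with Phi the
    diagonal of the stationary distribution of the transition matrix P.
    Requires a strongly connected digraph on >= 2 vertices so that P is
    irreducible and the eigenvalues real.
    """
    n = g.num_vertices
    if n < 2:
        raise ValueError("Chung Laplacian needs >= 2 vertices")
    if len(largest_scc(g)) != n:
        raise ValueError(
            "digraph is not strongly connected; restrict to the largest "
            "strongly connected component first"
        )
    p = transition_matrix(g)
    phi = _perron_vector(p)
    root = np.sqrt(phi)
    half = (root[:, None] * p / root[None, :])
    lap = np.eye(n) - (half + half.T) / 2.0
    return (lap + lap.T) / 2.0


def chung_spectral_gap(g: Digraph, tolerance: float = _TOL) -> float:
    """Smallest nonzero Chung Laplacian eigenvalue on the largest
    strongly connected component; 0 when that component is a single
    vertex."""
    scc = largest_scc(g)
    if len(scc) <= 1:
        return 0.0
    lap = chung_laplacian(induced_subgraph(g, scc))
    eig = np.linalg.eigvalsh(lap)
    floor = max(tolerance * float(np.max(np.abs(eig))), 1e-12)
    nonzero = eig[eig > floor]
    return float(nonzero.min()) if nonzero.size else 0.0


def _chung_spectral_radius(g: Digraph) -> float:
    scc = largest_scc(g)
    if len(scc) <= 1:
        return 0.0
    lap = chung_laplacian(induced_subgraph(g, scc))
    return float(np.max(np.abs(np.linalg.eigvalsh(lap))))


# ---------------------------------------------------------------------------
# code registry

_SPECTRAL_BASES = {
    # code prefix -> matrix factory taking (g, rev)
    "as": lambda g, rev: g.dense().astype(float),
    "tps": lambda g, rev: transition_matrix(g, reversed=rev),
    "bls": lambda g, rev: bauer_laplacian(g, reversed=rev),
}

# full list of recognised codes
PARAMETER_CODES = (
    "fcc", "tcc", "ec", "nbc", "size", "deg", "ind", "oud",
    "asg", "asg_low", "asr",
    "tpsg", "tpsg_low", "tpsg_rev", "tpsr", "tpsr_rev",
    "blsg", "blsg_low", "blsg_rev", "blsg_rev_low", "blsr", "blsr_rev",
    "clsg", "clsg_high", "clsr",
)

_CENTRE_CODES = frozenset({"fcc", "tcc", "deg", "ind", "oud"})


def requires_centre(code: str) -> bool:
    return code in _CENTRE_CODES


def _spectral_value(code: str, g: Digraph) -> float:
    if g.num_vertices < 2:
        return 0.0
    if code.startswith("cls"):
        if code == "clsg":
            return chung_spectral_gap(g)
        if code == "clsg_high":
            scc = largest_scc(g)
            if len(scc) <= 1:
                return 0.0
            lap = chung_laplacian(induced_subgraph(g, scc))
            return spectrum_summary(lap).gap_high
        if code == "clsr":
            return _chung_spectral_radius(g)
        raise KeyError(code)
    parts = code.split("_")
    base = parts[0]  # asg / asr / tpsg / ... : last char g or r
    rev = "rev" in parts[1:]
    which = "low" if "low" in parts[1:] else ("high" if "high" in parts[1:] else None)
    matrix = _SPECTRAL_BASES[base[:-1]](g, rev)
    summ = spectrum_summary(matrix)
    if base.endswith("r"):
        return summ.radius
    if which == "low":
        return summ.gap_low
    return summ.gap_high  # default "high" convention for asg/tpsg/blsg


def evaluate_parameter(
    code: str,
    g: Digraph,
    centre: int | None = None,
    flag_cap: int = 3,
    field_char: int = 2,
) -> float:
    """Evaluate the parameter named by ``code`` on the digraph ``g``.

    Centre-aware codes (``fcc``, ``tcc``, degrees) require ``centre``;
    all others apply to the graph as a whole.  Degenerate inputs (empty
    graphs, zero denominators, single-vertex spectra) evaluate to 0.
    """
    if code not in PARAMETER_CODES:
        raise KeyError(
            f"unknown parameter code {code!r}; valid codes: "
            + ", ".join(PARAMETER_CODES)
        )
    if code in _CENTRE_CODES:
        if centre is None:
            raise ValueError(f"parameter {code!r} requires a centre vertex")
        if g.num_vertices == 0:
            return 0.0
        if code == "fcc":
            return fagiolo_cc(g, centre)
        if code == "tcc":
            return transitive_cc(g, centre)
        prof = degree_profile(g, centre)
        return float({"deg": prof.deg, "ind": prof.ind, "oud": prof.oud}[code])
    if code == "size":
        return float(size_param(g))
    if code == "ec":
        return float(euler_characteristic(build_complex(g, max_dim=flag_cap)))
    if code == "nbc":
        if g.num_vertices == 0:
            return 0.0
        bv = betti_numbers(build_complex(g, max_dim=flag_cap), field_char)
        return normalised_betti_coefficient(bv)
    return _spectral_value(code, g)
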
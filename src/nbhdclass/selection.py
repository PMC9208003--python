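"""Ranking vertices by selection parameters and picking neighbourhoods.

Each vertex is scored by evaluating a parameter on its closed
neighbourhood (centre-aware parameters at the centre); the top or
bottom M scorers give the M neighbourhoods used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digraph import Digraph, Neighbourhood, closed_neighbourhood
from .parameters import evaluate_parameter, requires_centre

__all__ = [
    "SelectionSpec",
    "RankedList",
    "parameter_table",
    "rank_vertices",
    "select_neighbourhoods",
]


@dataclass(frozen=True)
class SelectionSpec:
    parameter: str
    count: int
    direction: str = "top"  # "top" or "bottom"

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.direction not in ("top", "bottom"):
            raise ValueError("direction must be 'top' or 'bottom'")


@dataclass(frozen=True)
class RankedList:
    entries: tuple[tuple[int, float], ...]  # (vertex id, value), rank order

    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(v for v, _ in self.entries)


def parameter_table(
    g: Digraph, codes: list[str], flag_cap: int = 3
) -> pd.DataFrame:
    """Evaluate each code on the closed neighbourhood of every vertex.

    Returns a DataFrame indexed by vertex id with one column per code.
    """
    nbhds = [closed_neighbourhood(g, v) for v in range(g.num_vertices)]
    data = {}
    for code in codes:
        centreish = requires_centre(code)
        vals = np.empty(g.num_vertices)
        for v, nb in enumerate(nbhds):
            centre = nb.local_centre if centreish else None
            vals[v] = evaluate_parameter(
                code, nb.subgraph, centre=centre, flag_cap=flag_cap
            )
        data[code] = vals
    table = pd.DataFrame(data, index=pd.RangeIndex(g.num_vertices, name="vertex_id"))
    return table


def rank_vertices(values, direction: str = "top") -> RankedList:
    """Sort vertices by value (descending for 'top'), ties by ascending id."""
    vals = np.asarray(values, dtype=float)
    ids = np.arange(len(vals))
    key = -vals if direction == "top" else vals
    order = np.lexsort((ids, key))
    return RankedList(
        entries=tuple((int(i), float(vals[i])) for i in order)
    )


def select_neighbourhoods(
    g: Digraph, spec: SelectionSpec, table: pd.DataFrame
) -> list[Neighbourhood]:
    """The M neighbourhoods whose centres rank highest (or lowest)."""
    if spec.count > g.num_vertices:
        raise ValueError(
            f"cannot select {spec.count} neighbourhoods from "
            f"{g.num_vertices} vertices"
        )
    values = table[spec.parameter].to_numpy()
    ranked = rank_vertices(values, spec.direction)
    centres = ranked.vertices[: spec.count]
    return [closed_neighbourhood(g, v) for v in centres]


def write_selection_csv(ranked: RankedList, spec: SelectionSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# parameter={spec.parameter} count={spec.count} "
                 f"direction={spec.direction}\n")
        fh.write("rank,vertex_id,value\n")
        for rank, (v, val) in enumerate(ranked.entries[: spec.count]):
            fh.write(f"{rank},{v},{val!r}\n")
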
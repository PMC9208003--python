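"""Binary dynamics on digraphs and their vector summaries.

A binary dynamics is a piecewise-constant map from time to the set of
active vertices, stored here as a set of (vertex, time) spike events.
Encoding proceeds in three steps: partition a time interval into equal
half-open bins, induce the active subgraph of each selected
neighbourhood in each bin, and apply a feature parameter to every
active subgraph, yielding an M x K feature matrix per dynamics
instance.  Column concatenation turns the matrix into the vector
summary consumed by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digraph import Digraph, Neighbourhood, induced_subgraph
from .parameters import evaluate_parameter, requires_centre

__all__ = [
    "BinaryDynamics",
    "BinSpec",
    "BinaryState",
    "FeatureMatrix",
    "make_bins",
    "binary_state",
    "active_subgraph",
    "featurise",
    "vector_summary",
    "read_spikes",
    "write_spikes_tsv",
    "read_labels",
    "write_labels_csv",
]


@dataclass(frozen=True)
class BinaryDynamics:
    """Spike events (vertex id, time in ms) over one labelled window."""

    vertices: np.ndarray  # int vertex ids
    times: np.ndarray  # float ms, window-relative
    duration: float
    label: object = None

    def __post_init__(self):
        object.__setattr__(
            self, "vertices", np.asarray(self.vertices, dtype=np.int64)
        )
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.vertices.shape != self.times.shape:
            raise ValueError("vertices and times must have equal length")
        if self.times.size and (
            self.times.min() < 0 or self.times.max() >= self.duration
        ):
            raise ValueError("spike times must lie in [0, duration)")

    @property
    def num_spikes(self) -> int:
        return int(self.vertices.size)

    def active_in(self, start: float, end: float) -> frozenset[int]:
        """Vertices with at least one spike in the half-open bin [start, end)."""
        mask = (self.times >= start) & (self.times < end)
        return frozenset(np.unique(self.vertices[mask]).tolist())


@dataclass(frozen=True)
class BinSpec:
    """K equal half-open bins partitioning the interval [a, b)."""

    interval: tuple[float, float]
    num_bins: int
    bin_edges: tuple[float, ...] = field(init=False)

    def __post_init__(self):
        a, b = self.interval
        if not b > a:
            raise ValueError(f"interval [{a}, {b}] has non-positive width")
        if self.num_bins < 1:
            raise ValueError("num_bins must be >= 1")
        edges = np.linspace(a, b, self.num_bins + 1)
        object.__setattr__(self, "bin_edges", tuple(float(e) for e in edges))

    def bins(self) -> list[tuple[float, float]]:
        e = self.bin_edges
        return [(e[k], e[k + 1]) for k in range(self.num_bins)]


@dataclass(frozen=True)
class BinaryState:
    """The set of active vertices within one subgraph and one bin."""

    active: frozenset[int]


def make_bins(interval, num_bins: int) -> BinSpec:
    return BinSpec(interval=(float(interval[0]), float(interval[1])),
                   num_bins=int(num_bins))


def binary_state(d: BinaryDynamics, members, bin_interval) -> BinaryState:
    """Members with at least one spike inside the half-open bin."""
    start, end = bin_interval
    return BinaryState(active=d.active_in(start, end) & frozenset(members))


def active_subgraph(nbhd: Neighbourhood, state: BinaryState) -> Digraph:
    """Subgraph of the neighbourhood induced by its active vertices.

    The centre is included only if it spiked.  Returned in ambient-free
    local coordinates of the neighbourhood subgraph.
    """
    if not state.active <= nbhd.members:
        raise ValueError("active vertices must be neighbourhood members")
    local = [i for i, m in enumerate(nbhd.member_map) if m in state.active]
    return induced_subgraph(nbhd.subgraph, local)


@dataclass(frozen=True)
class FeatureMatrix:
    """M x K matrix of feature-parameter values, rows = neighbourhoods."""

    values: np.ndarray
    selection_code: str | None = None
    feature_code: str | None = None
    instance_id: int | None = None


def featurise(
    d: BinaryDynamics,
    nbhds: list[Neighbourhood],
    bins: BinSpec,
    feature_code: str,
    flag_cap: int = 3,
    selection_code: str | None = None,
    instance_id: int | None = None,
) -> FeatureMatrix:
    """Apply the feature parameter to every active subgraph.

    Entry (m, k) is the parameter value on the active subgraph of
    neighbourhood m in bin k; an empty active subgraph scores 0, and a
    centre-relative parameter scores 0 whenever the centre is silent.
    """
    if not nbhds:
        raise ValueError("need at least one neighbourhood")
    centreish = requires_centre(feature_code)
    values = np.zeros((len(nbhds), bins.num_bins))
    for k, (start, end) in enumerate(bins.bins()):
        window_active = d.active_in(start, end)
        for m, nb in enumerate(nbhds):
            active = frozenset(window_active & nb.members)
            if not active:
                continue
            if centreish and nb.centre not in active:
                continue
            sub_members = sorted(active)
            local = [i for i, mm in enumerate(nb.member_map) if mm in active]
            sub = induced_subgraph(nb.subgraph, local)
            centre = sub_members.index(nb.centre) if centreish else None
            values[m, k] = evaluate_parameter(
                feature_code, sub, centre=centre, flag_cap=flag_cap
            )
    return FeatureMatrix(
        values=values,
        selection_code=selection_code,
        feature_code=feature_code,
        instance_id=instance_id,
    )


def vector_summary(f: FeatureMatrix) -> np.ndarray:
    """Column concatenation of the M x K matrix into a length-MK vector."""
    return np.asarray(f.values).ravel(order="F")


# ---------------------------------------------------------------------------
# file formats

def read_spikes(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TSV spike file ``vertex_id<TAB>time_ms``; '#' comments
    allowed; returned sorted by time then vertex."""
    verts, times = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            v, t = line.split()[:2]
            verts.append(int(v))
            times.append(float(t))
    v = np.asarray(verts, dtype=np.int64)
    t = np.asarray(times, dtype=float)
    order = np.lexsort((v, t))
    return v[order], t[order]


def write_spikes_tsv(vertices, times, path) -> None:
    with open(path, "w") as fh:
        fh.write("# vertex_id\ttime_ms\n")
        for v, t in zip(vertices, times):
            fh.write(f"{int(v)}\t{float(t):.6f}\n")


def read_labels(path) -> list[tuple[int, float, float, object]]:
    """Read the label CSV ``window_index,start_ms,end_ms,label``."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("window_index"):
            fh.seek(0)
        for line in fh:
            line = line.strip()
            if not line:
                continue
            idx, start, end, label = line.split(",")[:4]
            rows.append((int(idx), float(start), float(end), label))
    return rows


def write_labels_csv(windows, path) -> None:
    """``windows`` is an iterable of (start_ms, end_ms, label) triples."""
    with open(path, "w") as fh:
        fh.write("window_index,start_ms,end_ms,label\n")
        for i, (start, end, label) in enumerate(windows):
            fh.write(f"{i},{float(start):.6f},{float(end):.6f},{label}\n")


def write_features_csv(vectors, labels, path) -> None:
    """One row per instance: ``instance_id,label,f0,...,f{MK-1}``."""
    vectors = np.asarray(vectors, dtype=float)
    with open(path, "w") as fh:
        width = vectors.shape[1] if vectors.ndim == 2 else 0
        header = ",".join(f"f{i}" for i in range(width))
        fh.write(f"instance_id,label,{header}\n")
        for i, (row, label) in enumerate(zip(vectors, labels)):
            values = ",".join(repr(float(x)) for x in row)
            fh.write(f"{i},{label},{values}\n")
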
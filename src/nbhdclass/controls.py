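"""Validation controls for the neighbourhood classification pipeline.

Five experiments probe whether informed neighbourhood selection is
doing real work:

- random selection: neighbourhoods of uniformly chosen centres;
- centres only: binary fired/silent features of the ranked centres,
  discarding the neighbourhoods entirely;
- degree-matched subgraphs: per centre, a subgraph induced by the centre
  plus as many random vertices as it has neighbours;
- fake neighbourhoods: rewire each centre's in- and out-arcs to random
  targets (degrees preserved) and take neighbourhoods in the modified
  graph;
- shuffled activity: precompose every dynamics with a fixed vertex
  permutation, breaking the alignment between structure and activity.

Each control feeds the unchanged downstream pipeline, differing only in
where the neighbourhoods or the dynamics come from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .classify import LabelledDataset, build_dataset, split_dataset, \
    train_and_score
from .digraph import Digraph, Neighbourhood, closed_neighbourhood, \
    induced_subgraph
from .encoding import BinaryDynamics, BinSpec

__all__ = [
    "ControlSpec",
    "random_selection_control",
    "centres_only_features",
    "degree_matched_subgraphs",
    "fake_neighbourhoods",
    "shuffle_activity",
    "run_control",
]

CONTROL_KINDS = (
    "random_selection",
    "centres_only",
    "degree_matched",
    "fake_neighbourhood",
    "shuffled_activity",
)


@dataclass(frozen=True)
class ControlSpec:
    kind: str
    iterations: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CONTROL_KINDS:
            raise ValueError(
                f"unknown control kind {self.kind!r}; valid: {CONTROL_KINDS}"
            )
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def random_selection_control(
    g: Digraph, m: int, seed: int | np.random.Generator = 0
) -> list[Neighbourhood]:
    """Neighbourhoods of M uniformly sampled distinct centres."""
    if m > g.num_vertices:
        raise ValueError("cannot sample more centres than vertices")
    rng = np.random.default_rng(seed)
    centres = rng.choice(g.num_vertices, size=m, replace=False)
    return [closed_neighbourhood(g, int(v)) for v in centres]


def centres_only_features(
    d: BinaryDynamics, centres: list[int], bins: BinSpec
) -> np.ndarray:
    """Binary M x K matrix: entry (m, k) = 1 iff centre m fired in bin k."""
    values = np.zeros((len(centres), bins.num_bins))
    for k, (start, end) in enumerate(bins.bins()):
        active = d.active_in(start, end)
        for m, c in enumerate(centres):
            values[m, k] = 1.0 if c in active else 0.0
    return values


def degree_matched_subgraphs(
    g: Digraph, centres: list[int], seed: int | np.random.Generator = 0
) -> list[Neighbourhood]:
    """Per centre of degree d: the subgraph induced by the centre plus d
    random non-centre vertices, matching the true neighbourhood's vertex
    count but otherwise unrelated to the centre."""
    rng = np.random.default_rng(seed)
    out = []
    n = g.num_vertices
    for c in centres:
        nb = closed_neighbourhood(g, c)
        d = nb.size - 1
        pool = np.delete(np.arange(n), c)
        members = np.union1d(rng.choice(pool, size=d, replace=False), [c])
        out.append(
            Neighbourhood(
                centre=c,
                subgraph=induced_subgraph(g, members),
                member_map=tuple(int(v) for v in members),
            )
        )
    return out


def fake_neighbourhoods(
    g: Digraph, centres: list[int], seed: int | np.random.Generator = 0
) -> tuple[Digraph, list[Neighbourhood]]:
    """Rewire every centre's arcs to random endpoints, preserving its in-
    and out-degree, then extract the centres' new closed neighbourhoods.

    Implemented as a random permutation of each centre's adjacency row
    (out-arcs) and column (in-arcs), restricted to positions that are
    neither the centre itself (no self-loops) nor another centre (so
    every centre's degrees stay intact).  Permuting boolean entries
    cannot create duplicate arcs, so the graph stays simple.
    """
    rng = np.random.default_rng(seed)
    dense = g.adjacency.toarray()
    n = g.num_vertices
    centre_set = set(int(c) for c in centres)
    for c in centre_set:
        free = np.array([v for v in range(n) if v != c and v not in centre_set])
        if free.size:
            dense[c, free] = dense[c, rng.permutation(free)]
            dense[free, c] = dense[rng.permutation(free), c]
    modified = Digraph(sp.csr_matrix(dense))
    nbhds = [closed_neighbourhood(modified, int(c)) for c in centres]
    return modified, nbhds


def shuffle_activity(
    dynamics: list[BinaryDynamics], sigma
) -> list[BinaryDynamics]:
    """Relabel spikes: vertex sigma[i] receives the spike train of i.

    Labels and times are preserved, so applying the inverse permutation
    reconstructs the original activity exactly.
    """
    sigma = np.asarray(sigma, dtype=np.int64)
    if not np.array_equal(np.sort(sigma), np.arange(sigma.size)):
        raise ValueError("sigma must be a permutation of all vertex ids")
    out = []
    for d in dynamics:
        v = sigma[d.vertices]
        order = np.lexsort((v, d.times))
        out.append(
            BinaryDynamics(
                vertices=v[order],
                times=d.times[order],
                duration=d.duration,
                label=d.label,
            )
        )
    return out


def run_control(
    g: Digraph,
    dynamics: list[BinaryDynamics],
    spec: ControlSpec,
    nbhds: list[Neighbourhood],
    bins: BinSpec,
    feature_code: str,
    flag_cap: int = 3,
    train_fraction: float = 0.6,
):
    """Run one control through the unchanged downstream pipeline.

    ``nbhds`` are the informed neighbourhoods (used for centre lists,
    degree matching, and the fake-neighbourhood rewiring).  Returns a
    list of ClassificationReport, one per iteration.
    """
    reports = []
    rng = np.random.default_rng(spec.seed)
    centres = [nb.centre for nb in nbhds]
    for _ in range(spec.iterations):
        it_seed = int(rng.integers(2**31 - 1))
        if spec.kind == "random_selection":
            use_nbhds = random_selection_control(g, len(nbhds), it_seed)
            use_dyn = dynamics
        elif spec.kind == "degree_matched":
            use_nbhds = degree_matched_subgraphs(g, centres, it_seed)
            use_dyn = dynamics
        elif spec.kind == "fake_neighbourhood":
            _, use_nbhds = fake_neighbourhoods(g, centres, it_seed)
            use_dyn = dynamics
        elif spec.kind == "shuffled_activity":
            sigma = np.random.default_rng(it_seed).permutation(g.num_vertices)
            use_nbhds = nbhds
            use_dyn = shuffle_activity(dynamics, sigma)
        elif spec.kind == "centres_only":
            vectors = np.stack([
                centres_only_features(d, centres, bins).ravel(order="F")
                for d in dynamics
            ])
            labels = np.asarray([d.label for d in dynamics])
            ds = LabelledDataset(vectors, labels)
            train, test = split_dataset(ds, train_fraction, it_seed)
            reports.append(
                train_and_score(train, test, seed=it_seed,
                                feature_code="centre_binary",
                                m=len(centres), k=bins.num_bins)
            )
            continue
        ds = build_dataset(use_dyn, use_nbhds, bins, feature_code,
                           flag_cap=flag_cap)
        train, test = split_dataset(ds, train_fraction, it_seed)
        reports.append(
            train_and_score(train, test, seed=it_seed,
                            feature_code=feature_code,
                            m=len(use_nbhds), k=bins.num_bins)
        )
    return reports
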
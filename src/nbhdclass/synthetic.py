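"""Synthetic labelled spiking activity on random digraphs.

Emulates a stimulus-classification experiment on an artificial spiking
network: an Erdős–Rényi digraph, eight stimulus classes each exciting a
fixed random subset (10%) of vertices, stimuli injected one per 200 ms
window in shuffled order with a jittered onset in the first 10 ms, a
random strength multiplier in [1, 2], and background noise throughout.

Propagation is a discrete-time probabilistic cascade with synaptic
integration: each vertex carries an input trace that decays
exponentially and accumulates, per 1 ms step, a gain times the number
of in-neighbours that fired in the previous step, the external stimulus
drive (for afferents of the window's class, during the stimulus), and a
constant background term.  A non-refractory vertex fires with
probability 1 - exp(-trace); firing resets the trace and starts a
refractory/adaptation period.  With the default slow trace and long
refractory period, each stimulus launches a slow ignition wave through
the graph, so spike timing encodes graph distance from the stimulated
subset -- the regime in which neighbourhood-level readouts are
informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .digraph import Digraph
from .encoding import BinaryDynamics, write_labels_csv, write_spikes_tsv

__all__ = [
    "StimulusDesign",
    "StimulusSchedule",
    "PropagationParams",
    "erdos_renyi_digraph",
    "make_design",
    "make_schedule",
    "simulate",
    "write_spikes",
    "generate_dataset",
]


@dataclass(frozen=True)
class StimulusDesign:
    """Per class, the fixed vertex subset receiving the stimulus drive."""

    afferents: tuple[tuple[int, ...], ...]
    seed: int

    @property
    def num_classes(self) -> int:
        return len(self.afferents)


@dataclass(frozen=True)
class StimulusSchedule:
    """Consecutive labelled windows with per-window onset and strength."""

    windows: tuple[tuple[float, float, int], ...]  # (start, end, label)
    onsets: tuple[float, ...]  # jittered stimulus onset, window-relative ms
    strengths: tuple[float, ...]  # multiplier drawn uniformly from [1, 2)
    window_ms: float
    stimulus_ms: float

    @property
    def num_windows(self) -> int:
        return len(self.windows)

    def labels(self) -> tuple[int, ...]:
        return tuple(lab for _, _, lab in self.windows)


@dataclass(frozen=True)
class PropagationParams:
    """Cascade parameters; inputs accumulate per step (default 1 ms).

    ``decay`` is the per-step retention of the input trace (0.95 gives a
    ~20 ms integration time constant); ``refractory_steps`` lumps the
    absolute refractory period and spike-frequency adaptation into one
    silent interval, so a vertex fires at most a few times per 200 ms
    window.
    """

    step_ms: float = 1.0
    gain: float = 0.08  # input weight per firing in-neighbour
    drive: float = 3.0  # external input to an afferent during its stimulus
    background_rate: float = 2e-5  # noise input per vertex per step
    refractory_steps: int = 60
    decay: float = 0.95  # per-step input trace retention


def erdos_renyi_digraph(n: int, p: float, seed: int | np.random.Generator = 0) -> Digraph:
    """Each ordered pair (u, v), u != v, is an arc independently with
    probability p."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    return Digraph(sp.csr_matrix(mask))


def make_design(
    g: Digraph,
    num_classes: int = 8,
    fraction: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> StimulusDesign:
    """Draw an independent uniform afferent subset per stimulus class."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    size = round(fraction * g.num_vertices)
    sets = tuple(
        tuple(sorted(rng.choice(g.num_vertices, size=size, replace=False).tolist()))
        for _ in range(num_classes)
    )
    seed_val = seed if isinstance(seed, int) else -1
    return StimulusDesign(afferents=sets, seed=seed_val)


def make_schedule(
    num_classes: int = 8,
    repeats: int = 500,
    window_ms: float = 200.0,
    stimulus_ms: float = 5.0,
    onset_jitter_ms: float = 10.0,
    strength_range: tuple[float, float] = (1.0, 2.0),
    seed: int | np.random.Generator = 0,
) -> StimulusSchedule:
    """Shuffled sequence of ``num_classes * repeats`` stimulus windows."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(num_classes), repeats)
    rng.shuffle(labels)
    n = labels.size
    starts = np.arange(n) * window_ms
    windows = tuple(
        (float(s), float(s + window_ms), int(lab))
        for s, lab in zip(starts, labels)
    )
    onsets = tuple(float(x) for x in rng.uniform(0, onset_jitter_ms, size=n))
    lo, hi = strength_range
    strengths = tuple(float(x) for x in rng.uniform(lo, hi, size=n))
    return StimulusSchedule(
        windows=windows,
        onsets=onsets,
        strengths=strengths,
        window_ms=window_ms,
        stimulus_ms=stimulus_ms,
    )


def simulate(
    g: Digraph,
    design: StimulusDesign,
    schedule: StimulusSchedule,
    params: PropagationParams = PropagationParams(),
    seed: int | np.random.Generator = 0,
) -> list[BinaryDynamics]:
    """Run the cascade over every window; returns one labelled
    BinaryDynamics per window with window-relative spike times."""
    rng = np.random.default_rng(seed)
    n = g.num_vertices
    at = sp.csr_matrix(g.adjacency.T).astype(np.float64)
    steps = int(round(schedule.window_ms / params.step_ms))
    out: list[BinaryDynamics] = []
    afferent_masks = []
    for members in design.afferents:
        mask = np.zeros(n, dtype=bool)
        mask[list(members)] = True
        afferent_masks.append(mask)
    for w, (start, end, label) in enumerate(schedule.windows):
        onset = schedule.onsets[w]
        strength = schedule.strengths[w]
        drive_mask = afferent_masks[label]
        active = np.zeros(n, dtype=bool)
        refrac = np.zeros(n, dtype=np.int64)
        trace = np.zeros(n)
        sp_v: list[np.ndarray] = []
        sp_t: list[np.ndarray] = []
        for t in range(steps):
            tm = t * params.step_ms
            x = params.gain * (at @ active.astype(np.float64))
            x += params.background_rate
            if onset <= tm < onset + schedule.stimulus_ms:
                x = x + drive_mask * (params.drive * strength)
            trace = params.decay * trace + x
            prob = 1.0 - np.exp(-trace)
            fire = (rng.random(n) < prob) & (refrac == 0)
            refrac = np.maximum(refrac - 1, 0)
            refrac[fire] = params.refractory_steps
            trace[fire] = 0.0
            active = fire
            idx = np.flatnonzero(fire)
            if idx.size:
                sp_v.append(idx)
                sp_t.append(np.full(idx.size, tm))
        verts = np.concatenate(sp_v) if sp_v else np.empty(0, dtype=np.int64)
        times = np.concatenate(sp_t) if sp_t else np.empty(0)
        order = np.lexsort((verts, times))
        out.append(
            BinaryDynamics(
                vertices=verts[order],
                times=times[order],
                duration=schedule.window_ms,
                label=label,
            )
        )
    return out


def write_spikes(dynamics, schedule: StimulusSchedule, spikes_path, labels_path):
    """Emit the global spike TSV (absolute times) and the label CSV."""
    verts, times = [], []
    for d, (start, _end, _lab) in zip(dynamics, schedule.windows):
        verts.append(d.vertices)
        times.append(d.times + start)
    v = np.concatenate(verts) if verts else np.empty(0, dtype=np.int64)
    t = np.concatenate(times) if times else np.empty(0)
    write_spikes_tsv(v, t, spikes_path)
    write_labels_csv(
        [(s, e, lab) for s, e, lab in schedule.windows], labels_path
    )


def generate_dataset(
    n: int = 1000,
    p: float = 0.01,
    num_classes: int = 8,
    repeats: int = 500,
    fraction: float = 0.1,
    params: PropagationParams = PropagationParams(),
    seed: int = 0,
) -> tuple[Digraph, StimulusDesign, StimulusSchedule, list[BinaryDynamics]]:
    """End-to-end convenience: graph, design, schedule and simulation,
    all driven by independent streams derived from one seed."""
    root = np.random.default_rng(seed)
    g_seed, d_seed, s_seed, sim_seed = root.spawn(4)
    g = erdos_renyi_digraph(n, p, g_seed)
    design = make_design(g, num_classes, fraction, d_seed)
    schedule = make_schedule(num_classes, repeats, seed=s_seed)
    dyn = simulate(g, design, schedule, params, sim_seed)
    return g, design, schedule, dyn
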
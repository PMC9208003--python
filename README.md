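# nbhdclass

Classification of binary dynamics on directed graphs through the graph
and topological invariants of vertex neighbourhoods.

## The problem

A *binary dynamics* on a digraph 𝒢 = (V, E) is a time course of binary
states, a map B : ℝ≥0 → 𝒫(V) assigning to each instant the set of
"active" vertices. The canonical example is spiking activity in a
network of neurons whose synaptic connectivity is the digraph. The
*signal classification problem* asks: given many labelled activity
windows (eight stimulus classes, say), predict the label of a held-out
window from the activity alone.

Raw binary states on a large graph are high-dimensional and noisy.
This package implements a neighbourhood-based summarisation: a small
number of *closed neighbourhoods* N_𝒢(v) — the subgraph induced by a
vertex v and all vertices adjacent to it in either direction — are
chosen by ranking all vertices with a **selection parameter** P, and
each activity window is condensed to the values of a **feature
parameter** Q on the *active subgraphs* of those neighbourhoods in a
few time bins.

Formally, for M selected neighbourhoods 𝓗₁, …, 𝓗_M and K time bins
I₁, …, I_K, the window B is encoded as the M × K matrix

    F_{m,k} = Q( 𝓗_{m,k} ),     𝓗_{m,k} = subgraph of 𝓗_m induced by
                                 { v : ∃ t ∈ I_k with v ∈ B(t) },

and the columns of F are concatenated into a vector summary of length
M·K that is fed to an RBF-kernel support-vector machine (one-vs-one,
stratified 60/40 train/test split, fivefold cross-validation on the
training portion).

## Parameters

Both P and Q are real-valued digraph invariants, addressable by code:

| code | invariant |
|------|-----------|
| `fcc` | Fagiolo clustering coefficient (directed triangles at the centre) |
| `tcc` | transitive clustering coefficient — directed 3-cliques at the centre over the attainable maximum `deg(deg−1) − ind·oud − R` |
| `ec`  | Euler characteristic of the directed flag complex |
| `nbc` | normalised Betti coefficient 𝔅 = Σᵢ (i+1)·βᵢ/sᵢ |
| `size` | vertex count |
| `asg` / `asr` | adjacency spectral gap / radius |
| `tpsg` / `tpsr` | transition-matrix spectral gap / radius |
| `blsg` / `blsr` | Bauer Laplacian spectral gap / radius |
| `clsg` / `clsr` | Chung Laplacian spectral gap / radius |

with `_low`/`_high` suffixes selecting the gap convention (smallest
nonzero modulus vs difference of the two largest moduli), `_rev`
swapping in- for out-degree normalisation, and `deg`/`ind`/`oud` degree
baselines. The directed flag complex of 𝒢 has the directed
(n+1)-cliques — vertex tuples whose arcs define a linear order — as its
n-simplices; Betti numbers are computed over GF(2) by default.

The package also ships the five validation controls (random selection,
centres-only binary features, degree-matched arbitrary subgraphs,
degree-preserving "fake neighbourhoods", and activity shuffled by a
vertex permutation) and a synthetic generator producing labelled
spiking activity on Erdős–Rényi digraphs: 8 stimulus classes, each
exciting a fixed random 10% of the vertices for 5 ms inside consecutive
200 ms windows with onset jitter, strength variation and background
noise, propagated by a seeded stochastic cascade with synaptic
integration. Everything is testable offline, no downloads.

## Worked example

```python
import nbhdclass as nc

g, design, schedule, dyn = nc.generate_dataset(
    n=300, p=0.01, num_classes=8, repeats=100, seed=42)
print(g)                       # Digraph(n=300, arcs=895)

table = nc.parameter_table(g, ["size", "asg"])
spec = nc.SelectionSpec("size", 20, "top")
report = nc.run_experiment(g, dyn, spec, "size",
                           nc.make_bins((10, 60), 2), seed=1)
print(report.accuracy)         # 0.7312
print(report.cv_range)         # (0.6875, 0.7917)
```

800 windows of simulated activity are encoded by the 20 largest closed
neighbourhoods into vectors of length 40 (20 neighbourhoods × 2 bins of
25 ms, skipping the first 10 ms of each window where the stimulus
itself is injected). The held-out accuracy of 73% against a chance
level of 12.5% shows that the neighbourhood counts alone carry most of
the stimulus identity. The same pipeline accepts real data: an
edge-list or MatrixMarket graph, a `vertex<TAB>time` spike file and a
window/label CSV.

A command-line interface mirrors the library:

```sh
nbhdclass simulate --n 300 --density 0.01 --repeats 100 --seed 42 --out-dir data/
nbhdclass classify --graph data/graph.tsv --spikes data/spikes.tsv \
    --labels data/labels.csv --selection size --feature size --count 20 \
    --seed 1 --out report.json
nbhdclass control --kind shuffled_activity --graph data/graph.tsv \
    --spikes data/spikes.tsv --labels data/labels.csv --count 20 \
    --seed 1 --out control.json
```

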
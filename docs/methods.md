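# Methods

## Digraphs and neighbourhoods

A digraph is finite and simple: reciprocal arcs are allowed, self-loops
and parallel arcs are not. Vertex ids are 0-based and contiguous; file
ids are remapped on load. The closed neighbourhood N_𝒢(v₀) is the
subgraph induced by v₀ and every vertex adjacent to it in either
direction, with v₀ as its *centre*; the open neighbourhood omits the
centre. Strongly connected components are computed with
`scipy.sparse.csgraph`; ties between equal-sized components are broken
towards the component containing the smallest vertex id, so all
selections are deterministic.

## Directed flag complex and homology

The n-simplices are the directed (n+1)-cliques: ordered tuples
(v₀, …, vₙ) with an arc vᵢ → vⱼ for all i < j. Enumeration extends each
tuple through the intersection of the out-neighbourhoods of its
vertices, in lexicographic order. Betti numbers βᵢ are the ranks of
simplicial homology computed from boundary-map ranks by sparse column
elimination over a prime field, GF(2) by default (a `field_char`
parameter accepts any prime, or 0 for rational coefficients via dense
rank). The Euler characteristic is the alternating sum of simplex
counts and equals the alternating sum of Betti numbers whenever the
complex is built without truncation; the property suite verifies this
identity on hundreds of random digraphs.

The normalised Betti coefficient 𝔅 = Σᵢ (i+1)·βᵢ/sᵢ weights homology by
the simplex count per dimension; dimensions with sᵢ = 0 contribute
nothing (βᵢ is necessarily 0 there). 𝔅 depends on the coefficient
field, so GF(2) values are only comparable with other GF(2) values.

The default dimension cap for pipeline use is 3: neighbourhood
complexes in dense graphs grow combinatorially, and truncation is
recorded on the result so capped Euler characteristics are
identifiable as such.

## Clustering coefficients

The Fagiolo coefficient at v₀ divides the count of directed-triangle
equivalence classes t→(v₀) = ½ Σ (a_ij+a_ji)(a_ik+a_ki)(a_jk+a_kj)
by deg(deg−1) − 2R, where R counts reciprocal neighbours.

The transitive clustering coefficient divides S₂(v₀), the number of
directed 3-cliques (transitive tournaments) containing v₀ — each
counted once per linear order, so a fully reciprocal triple contributes
six — by the attainable maximum deg(deg−1) − ind·oud − R. S₂ is
computed by direct enumeration of ordered triples through the
adjacency matrix; the closed-form expression sometimes quoted for it
(2t→ minus a cyclic-triple correction) double-counts on reciprocal
pairs and is documented as inconsistent in a unit test rather than
used. With the direct count, C_T lies in [0, 1] and attains 1 exactly
on complete reciprocal digraphs, which the test suite checks for 3–8
vertices against brute-force orientation enumeration.

## Spectral invariants

Four matrices are summarised by eigenvalue moduli: the adjacency
matrix, the transition matrix P = D_out⁻¹A (rows of sinks all-zero; the
reversed variant normalises by in-degree), the Bauer Laplacian
Δ = I − D_in⁻¹A with the whole row zeroed where ind = 0 (reversed:
out-degrees), and the Chung Laplacian
𝓛 = I − (Φ^½PΦ^−½ + Φ^−½P*Φ^½)/2, where Φ is the diagonal of the
stationary distribution φ of P (φP = φ, Σφ = 1, computed by
eigendecomposition with a damped power-iteration fallback).

The Chung Laplacian requires strong connectivity, so its gap and
radius are evaluated on the largest strongly connected component; a
component of size ≤ 1 scores 0. Spectral "gap" defaults to the
difference of the two largest moduli, with multiplicity (a repeated
leading modulus gives gap 0); the Chung gap is the smallest nonzero
eigenvalue. `_high`/`_low` suffixes override the convention per code.
An eigenvalue counts as nonzero when its modulus exceeds 1e−9 times
the spectral radius, with an absolute floor of 1e−12. Graphs with
fewer than two vertices score 0 on all spectral codes.

The property suite compares the Chung gap λ with the transition
spectrum through the Cheeger-style bounds
min_{i≠0}(1 − |ρᵢ|) ≤ 2λ and λ ≤ min_{i≠0}(1 − Re ρᵢ). The bare lower
bound without the factor 2 is violated on roughly a third of random
strongly connected digraphs and is therefore not asserted.

## Encoding and classification

Time bins are half-open, [a + (k−1)Δ′, a + kΔ′); a spike exactly at a
bin boundary belongs to the later bin. A vertex is active in a bin if
it spikes at least once inside it. The active subgraph of a
neighbourhood is the induced subgraph on its active members; the
centre participates only if it spiked. Features of empty active
subgraphs are 0, which preserves vector length and encodes silence;
centre-relative codes (`fcc`, `tcc`) also score 0 when the centre is
silent. The default encoding window is [10, 60] ms in two 25 ms bins:
the stimulus is injected in the first 10 ms of each window and the aim
is to classify the response, not the input.

The classifier is scikit-learn's `SVC` with default regularisation
(C = 1, RBF kernel width by the `scale` heuristic), one-vs-one
multiclass, no feature scaling. The 60/40 split is stratified by label
to avoid class starvation at small sample sizes, and fivefold
cross-validation runs on the training portion (folds are reduced when
a class has fewer members than folds). All randomness is seeded;
reports are bit-reproducible given data and seed.

## Synthetic experiment

The generator emulates a stimulus-classification experiment on an
artificial spiking network. An Erdős–Rényi digraph (1,000 vertices by
default; the scaled-down test configuration uses 300 at density 0.01)
carries 8 stimulus classes, each assigned an independent uniform 10%
subset of afferent vertices, so two classes share a given vertex with
probability 1%. Stimuli arrive in shuffled order, one per 200 ms
window, lasting 5 ms, with onset drawn uniformly from the first 10 ms
and strength multiplied by a uniform draw from [1, 2); background
noise runs throughout.

Propagation is a discrete-time stochastic cascade with synaptic
integration: each vertex keeps an input trace that retains a fraction
`decay` per 1 ms step and accumulates gain × (number of in-neighbours
that fired in the previous step) + external drive + background. A
non-refractory vertex fires with probability 1 − exp(−trace); firing
resets the trace and opens a refractory interval that lumps the
absolute refractory period and spike-frequency adaptation.

Defaults: gain 0.08, decay 0.95 (≈ 20 ms integration constant), drive
3.0, background 2e−5 per step, refractory 60 steps. In this regime a
stimulus launches a slow ignition wave: most vertices fire once per
window, at a latency that grows with graph distance from the class's
afferent set, so the response is location- and timing-coded rather
than rate-coded and the encoding bins read the wave front. The
parameters were fixed once so that the default seeded experiment is
classifiable well above chance but not perfectly, which is the regime
where selection and control comparisons are informative.

What the generator does **not** emulate: conductance-based or even
leaky-integrate-and-fire membrane dynamics, inhibition, synaptic
weights and delays, plasticity, and the biological heterogeneity of a
reconstructed circuit. Consequences measured on the defaults: the
informed pipeline reaches ~73–84% held-out accuracy (8 classes, chance
12.5%), and the shuffled-activity control drops by roughly 4–13
accuracy points rather than collapsing — in a sparse, locally
tree-like random graph much of the class signal lives in per-vertex
spike timing, which survives a vertex permutation, whereas in a
biological circuit single neurons are noisy and weakly tuned and
assembly structure carries the signal. Passing tests on synthetic data
therefore demonstrate the pipeline's mechanics and the direction of
the control effects, not the magnitudes attainable on real circuits.

## Validation controls

All five controls reuse the unchanged downstream pipeline and differ
only in where the neighbourhoods or the dynamics come from. The
fake-neighbourhood rewiring permutes each centre's adjacency row and
column over positions that are neither the centre itself nor another
centre, which preserves every centre's in- and out-degree, keeps the
graph simple, and leaves arcs between non-centres untouched. The
degree-matched control samples replacement members from all
non-centre vertices (the true neighbours are not excluded). Controls
report one score per iteration; mean and range mirror the usual
error-bar presentation.

## Problem sizes

The test suite and the acceptance script run the full pipeline at
n = 300, density 0.01, 8 × 100 windows, M = 20 neighbourhoods and
K = 2 bins — a configuration chosen to exercise every stage, including
selection, featurisation, classification and controls, at laptop
scale. Oracle suites use exhaustive enumeration up to 12 vertices and
randomised checks at a few hundred graphs per identity.
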
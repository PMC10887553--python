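# Methods

## The comparison problem

`dircomp` quantifies how different two directed, unweighted, simple graphs
are. Classical dissimilarities for digraphs compare pairwise quantities —
shortest-path statistics (portrait divergence, closeness) or propagation
affinities (DeltaCon). The measure at the core of this package instead
compares *higher-order* structure: the small induced subgraph patterns
(motifs, 2–4 nodes) that each node participates in.

## Motif catalogue

A motif class is an isomorphism class of weakly connected digraphs on 2–4
nodes. Classes are identified by a canonical code: the lexicographically
minimal row-major bit-string of the adjacency matrix over all node
permutations (at most 4! = 24, so exhaustive minimization is exact and
cheap). The complete enumerations contain 2 classes of size 2, 13 of size 3
(the connected triad census) and 199 of size 4.

The default catalogue has 35 classes: both size-2 classes, all 13 size-3
classes, and a packaged list of 20 four-node classes
(`src/dircomp/data/motif_catalogue.tsv`) — the 20 sparsest canonical
classes, ordered by edge count and then by code (all 8 three-edge classes
and the lexicographically first 12 of the four-edge classes). This
particular selection of four-node classes is a package convention: the
catalogue is data, every routine is generic over it, and
`build_catalogue(four_node="complete")` swaps in the full 199-class
enumeration (used in tests to verify that the census classifies every
enumerated instance). With the default catalogue, four-node instances
outside the 20 classes are excluded from counts and reported in a per-node
diagnostic tally.

## Census

Motif instances are **induced**, weakly connected subgraphs, each counted
once. Induced (rather than partial) matching keeps classes mutually
exclusive, in line with standard triad-census practice. Enumeration is an
ESU-style search on the symmetrized adjacency, held as per-node bitmasks;
classification packs the induced adjacency into an integer and looks it up
in a precomputed table covering all 2^(k(k-1)) labeled digraphs on k nodes,
so no canonicalization happens in the inner loop. The census is validated
against an exhaustive all-subsets oracle on small random digraphs.

The per-node counts row-normalize to the motif distribution matrix **T**
(N × 35): `T[i, j]` is the fraction of node *i*'s motif participations that
fall in class *j*. Normalization is per node across all catalogue columns
jointly; nodes with no motif participation (isolated nodes) keep an
all-zero row and stay in N.

## Dissimilarity

For one graph, the generalized Jensen–Shannon divergence of the N rows of T,

    zeta(T) = (1/N) * sum_ij T[i,j] * ln(T[i,j] / mu_j),    mu = column mean,

lies in [0, ln N] and vanishes iff all rows coincide. The **directed
network node dispersion** DNND(G) = zeta(T) / ln(N+1) rescales it to
[0, 1): 0 for vertex-transitive graphs (directed cycles), larger for graphs
with heterogeneous node environments.

Two graphs are compared by

    Dm(G1, G2) = phi * JSD(mu1, mu2) / ln 2  +  (1 - phi) * |DNND1 - DNND2|

with natural logarithms throughout. Conventions worth stating:

* The global term is the standard two-distribution Jensen–Shannon
  divergence with mixture (mu1 + mu2)/2, which lies in [0, ln 2]; dividing
  by ln 2 maps it to [0, 1]. Each mu is renormalized to sum 1 first, so it
  is a probability distribution even when zero-participation nodes depress
  the raw column means.
* The local term is the absolute DNND difference — a dissimilarity must be
  non-negative. No square-root transform is applied to DNND (the undirected
  dissimilarity lineage this extends sometimes uses one); the plain
  difference keeps the two-term decomposition affine in phi.
* Both terms are size-free; graphs of different N are comparable, each DNND
  normalized by its own ln(N+1).
* Default phi = 0.5, weighting global and local structure equally; Dm is
  affine in phi, so a phi sweep costs one census per graph.

`motif_profile(G)` caches the census, mu and DNND of a graph for reuse
across many comparisons — the census is the only expensive step.

## dk-series null models

Null models randomize a graph while conserving chosen statistics; Dm should
shrink as the conserved set grows.

* **Dk1.0** — double-edge swaps `(u→v, x→y) ⇒ (u→y, x→v)`; preserves every
  in/out degree. Default chain length: 10 accepted swaps per edge, a
  standard mixing heuristic.
* **Dk2.0** — the same proposals, accepted only when the two targets (or
  the two sources) share the (in-degree, out-degree) class. Because swapped
  endpoints are exchangeable within a class, the joint degree distribution
  over edges (the multiset of source-class/target-class pairs) is
  conserved exactly. Proposals are drawn by rejection; on graphs where
  every node has a distinct degree pair no swap is legal and the input is
  returned unchanged.
* **Dk2.5** — a chain of Dk2.0-legal swaps with Metropolis acceptance on
  the energy E = L1 distance between the current and original
  degree-dependent clustering curves: downhill moves always accepted,
  uphill with probability exp(-dE/T). Defaults: 10 sweeps of M legal
  proposals, initial temperature 0.01, geometric cooling 0.995 per sweep,
  tolerance 0.05. The chain starts from the input graph (E = 0); after
  annealing, greedy downhill sweeps run until E is at or below tolerance
  (up to 20 extra sweeps) and the report records the final E. Zero sweeps
  return the input unchanged. The energy is evaluated on the dense
  symmetrized adjacency (O(N^3) per proposal via one matrix product), which
  is the right trade-off for the graph sizes this package targets
  (hundreds of nodes).

A strict-novelty rule — a swap may not re-create an edge of the *original*
input graph — is enforced per accepted swap and on by default, with an
escape hatch (`strict_novelty=False`, CLI `--no-strict-novelty`) because
dense graphs can make the constraint infeasible; every realization's report
records the mode, the attempt/accept counts and post-hoc conservation
checks. Chains that exhaust their attempt budget return the best-effort
graph with `target_reached=False` rather than raising.

### Clustering coefficient

The directed clustering coefficient is the all-triangle directed
coefficient

    C_i = [(A + A^T)^3]_ii / (2 * (d_tot * (d_tot - 1) - 2 * d_recip)),

which counts all directed triangle configurations through node *i* against
the number of possible ones, discounting reciprocal pairs; C_i := 0 when
the denominator vanishes (degree ≤ 1, or all partners reciprocal). This
definition reproduces the worked 9-node example packaged as
`clustered_toy9()`: per-node coefficients {1/2, 1/6, 0, 0, 1/6, 0, 0, 0, 0}
for total degrees {2, 3, 3, 3, 3, 1, 1, 1, 1}, hence degree-dependent curve
{1: 0, 2: 1/2, 3: 1/12}. The curve c̄(k) averages C_i over exactly the
nodes of total degree k, for the degrees present.

## Edge perturbation

`perturb(G, f)` adds (f > 0) or removes (f < 0) `round(|f| * M)` edges,
f ∈ [-0.9, 0.9]; additions are uniform over absent non-self-loop ordered
pairs, removals uniform over edges, the node set fixed. Rounding is
half-away-from-zero. Mean Dm between a graph and its perturbed copies
should increase with |f|.

## Baselines

* **Portrait divergence Dp.** B[l, k] counts nodes with exactly k nodes at
  directed BFS distance l (l = 0..diameter over reachable pairs); nodes
  with none at distance l land in k = 0, so rows sum to N, and unreachable
  pairs contribute to no row. For comparison, each row-stochastic Q = B/N
  is zero-padded to the common shape and divided by its own row count,
  giving a single distribution per graph; Dp is their Jensen–Shannon
  divergence. This flattening is the simplest construction that turns the
  per-row distributions into one; it is isolated in one function, and the
  original portrait-divergence row weighting is a known alternative.
* **DeltaCon Dd.** S = (I + eps^2 D - eps A)^{-1} with D the diagonal of
  total degrees and eps = 1/(1 + max total degree); Dd is the Frobenius
  distance of the two S matrices (no Matusita square roots).
* **Closeness Dc.** c_i = 1 / (sum of directed distances to reachable
  nodes), 0 when nothing is reachable; Dc is the L1 distance of the
  label-aligned closeness vectors.

Dd and Dc compare node-aligned matrices/vectors and therefore require
identical labeled node sets; the benchmarks only ever compare a graph with
its own rewired or perturbed variants, where this holds by construction.

## Synthetic data

All inputs are generated: Erdős–Rényi digraphs G(n, p) or G(n, m) stand in
for real networks, plus directed cycles, paths, stars, the mutual dyad and
the 9-node clustering toy. The benchmark condition used throughout the
experiments and the acceptance script is an ER digraph with N = 100 and
mean total degree 10 (p = 10/198 per ordered pair).

ER digraphs have no degree correlations, little clustering and a single
weakly connected component in the regime used; what they *cannot* show is
behaviour driven by heavy-tailed degrees, reciprocity structure or
community structure, all present in real directed networks. Consequently
the dk-series separation (mean Dm: dk1.0 ≥ dk2.0 ≥ dk2.5) is real but
numerically small on ER inputs — passing tests demonstrate correct
mechanics and orderings, not effect sizes transferable to empirical
networks.

## Experiment protocol and problem sizes

Experiment runners emit long-format records; realization r of condition c
uses seed `SeedSequence([master, counter]) % 2^31` with a global counter
over (condition, realization), so conditions never share random streams and
every record is reproducible in isolation from its stored seed. Defaults
follow the benchmark protocol (100 realizations, phi ∈ {0.1, 0.3, 0.5,
0.7, 0.9}, f ∈ {±0.1, ..., ±0.9}); the test suite and the acceptance
script use 20–50 realizations, the package's desk-scale profile (also
available as `--quick` in the CLI), which keeps a full run in minutes on
one core while leaving the stochastic orderings stable.

## Numerical choices

* Natural logarithms everywhere; 0·ln 0 := 0; divergences are clamped at 0
  against negative round-off (~1e-16).
* T rows sum to 1 within 1e-12 or are exactly zero.
* Degenerate inputs: empty edge-list input is an error; an edgeless graph
  has no motifs, so its mean motif distribution is all-zero and comparing
  it raises rather than returning a spurious 0/0.
* Swap chains cap attempts at 100 per requested accepted swap.

## Known limitations

* The census is exact, not sampled; graphs with millions of edges are out
  of scope (the design targets up to ~10^4–10^5 nodes at modest density for
  sizes ≤ 3, less for size 4).
* Dk2.5's dense energy evaluation limits it to graphs of a few thousand
  nodes.
* Weighted, temporal and attributed graphs, motif sizes ≥ 5, and motif
  significance testing (z-scores against ensembles) are out of scope.
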
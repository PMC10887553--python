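# dircomp

Motif-based comparison of directed networks.

`dircomp` measures how dissimilar two directed, unweighted graphs are from
the small induced subgraph patterns (directed motifs, 2–4 nodes) their
nodes participate in — structure that edge- and path-based measures miss.
It is aimed at anyone who needs to tell directed networks apart or rank
their similarity: comparing a connectome, food web, email or transport
network against randomized null models, tracking how far a perturbed or
rewired network has drifted from its original, or benchmarking comparison
methods themselves.

## The measure

For a digraph G with N nodes, every node gets a motif distribution: the
fractions of its motif participations falling in each of the 35 default
motif classes (2 of size 2, 13 of size 3, 20 of size 4), collected in the
N × 35 matrix T. The generalized Jensen–Shannon divergence of the N rows,

    zeta(T) = (1/N) * Σ_ij T[i,j] ln( T[i,j] / mu_j ),   mu = column mean,

normalized as DNND(G) = zeta(T) / ln(N+1), is the *directed network node
dispersion* — 0 when all nodes have identical motif environments (a
directed cycle), approaching 1 for maximal heterogeneity. Two graphs are
compared by

    Dm(G1, G2) = phi * JSD(mu1, mu2) / ln 2 + (1 - phi) * |DNND1 - DNND2|,

a value in [0, 1]: the first (global) term compares the networks' mean
motif distributions, the second (local) term their node-dispersion; phi
(default 0.5) weights the two. Lower Dm means more similar networks.

The package also provides:

* **dk-series null models** — Dk1.0 (degree-preserving rewiring), Dk2.0
  (joint-degree-preserving) and Dk2.5 (additionally preserving the
  degree-dependent clustering curve via annealed swaps), plus a random
  edge-perturbation generator (add/remove a signed fraction f of edges).
* **Baselines** — portrait divergence Dp, DeltaCon Dd and closeness Dc.
* **Experiment runners** — seeded, reproducible null-model, perturbation
  and phi-sweep experiments with long-format CSV output.
* **CLI** — `dircomp census|compare|nullmodel|perturb|experiment`.

## Worked example

Compare an Erdős–Rényi digraph (N = 100, mean total degree 10) with a copy
from which half the edges were randomly removed:

```python
import dircomp as dc

G = dc.generate_er_digraph(100, p=10/198, seed=42)   # M = 507
H, spec = dc.perturb(G, -0.5, seed=0)                # M = 253
dc.write_edgelist(G, "er.tsv")
dc.write_edgelist(H, "er_perturbed.tsv")
```

```sh
$ dircomp compare er.tsv er_perturbed.tsv --method dm --phi 0.5
{
  "dm": 0.022791573212057402,
  "global_term": 0.01690554120679369,
  "local_term": 0.028677605217321114,
  "dnnd_1": 0.010266559904367744,
  "dnnd_2": 0.038944165121688856,
  "phi": 0.5
}
```

Removing half the edges left the mean motif usage nearly unchanged
(global term ≈ 0.017 of a possible 1) but almost quadrupled the node
dispersion (DNND 0.0103 → 0.0389): thinning an ER graph makes node
neighbourhoods more heterogeneous, and Dm = 0.023 averages the two effects
at phi = 0.5. The same pair under a baseline:

```sh
$ dircomp compare er.tsv er_perturbed.tsv --method portrait
{
  "portrait_divergence": 0.4130626740406639
}
```

In Python the pieces are available individually — `dc.motif_profile(G)`
caches the census for repeated comparisons, `dc.dm(G, H, phi=0.5)` returns
the full decomposition, `dc.dk25_rewire(G, seed=0)` returns a rewired graph
plus a conservation report, and `dc.run_perturbation_experiment(G,
realizations=100)` produces the benchmark table.

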
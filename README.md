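# hypermet

Metabolic networks are usually analyzed as standard graphs, but a
biochemical reaction links *all* of its reactants at once: the faithful
object is a hypergraph `H = (V, ℰ)` whose nodes are metabolites and
whose hyperedges are reactions (optionally bipartitioned into a
substrate *tail* and product *head*). Every popular "metabolic graph"
is an abstraction of this hypergraph — and several celebrated
topological findings (scale-free tails, the `C(k) ∝ k^-1` hierarchy
signature) turn out to depend on the abstraction and on what the null
model conserves. `hypermet` is a toolkit for running exactly that kind
of representation-sensitivity analysis, on real reaction lists or on
synthetic hypergraphs.

It is aimed at systems biologists and network scientists who want to
check whether a topological claim about a metabolic (or other
reaction-like) network survives (a) being computed on the hypergraph
itself rather than on a graph abstraction and (b) a null model that
conserves the reaction-size (hyperedge-cardinality) distribution.

## What is inside

* **Data model** (`hypermet.core`): hypergraphs with the structural
  primitives — node degree `d(v) = |ℳ(v)|`, neighborhoods `N(U)`,
  the binary incidence matrix `M`, the dual hypergraph (transpose of
  `M`), node removal for currency-metabolite experiments, and the
  sparsity bound `C(n, k)` on distinct cardinality-`k` hyperedges.
* **Abstractions** (`hypermet.transform`): primal (substance model,
  each reaction becomes a clique), cis-primal (substrate–substrate),
  trans-primal (substrate–product), the physical line graph
  transformation PLGT = primal ∘ dual (the reaction graph), and the
  enzyme/gene union transform.
* **Null models** (`hypermet.nullmodels`): seedable generators
  (fixed-cardinality random hypergraphs, exact-edge-count
  Erdős–Rényi graphs, metabolic-like hypergraphs with shifted-binomial
  reaction sizes) and three rewiring procedures conserving,
  respectively, the edge count, the full degree sequence, and the
  hyperedge cardinality multiset.
* **Clustering** (`hypermet.clustering`): Watts–Strogatz local and
  Barrat–Weigt global coefficients; the hypergraph coefficients
  `HC_local`/`HC_global` built on the *extra overlap*

  `EO(Eᵢ, Eⱼ) = (|D_ij ∩ N(D_ji)| + |D_ji ∩ N(D_ij)|) / (|D_ij| + |D_ji|)`,

  with `D_ij = Eᵢ − Eⱼ` — bounded in `[0, 1]` and reducing exactly to
  the classical coefficients when every hyperedge has cardinality 2 —
  plus the Estrada–Rodríguez-Velázquez (ERV) coefficient
  (hyper-triangles over 2-paths, unbounded above) for comparison, and
  `C(k)` curves with the minimal-clustering reference `γ_k = 2/(k²−k)`.
* **Statistics** (`hypermet.stats`): exact degree distributions,
  replica-ensemble percentile summaries, least-squares power-law tail
  fits `p(k) = βk^−α` with automatic or manual fitting regions, and
  the mod-(k−1) degree-class decomposition of the sparse-hypergraph
  "zig-zag" distribution head.
* **I/O + CLI** (`hypermet.io`, `hypermet.cli`): reaction TSV reader,
  hypergraph JSON, edge-list TSV, incidence TSV, and a `hypermet`
  command with `convert`, `rewire`, `synth`, `ensemble`, `degdist`,
  `cluster` and `fit` subcommands, each writing a reproducibility
  manifest.

## Worked example

Generate a metabolic-like hypergraph at the scale of the *E. coli*
network (1193 metabolites, 1168 reactions, reaction sizes from a
shifted binomial with mean 4.19 and support 2–10), compare graph and
hypergraph clustering, and rewire it under the cardinality-preserving
null model:

```python
import numpy as np
import hypermet as hm

H = hm.gen_binomial_hypergraph(n=1193, m=1168, mean_cardinality=4.19,
                               n_trials=8, seed=7)
G = hm.primal(H)
print(f"primal: {G.l} edges, mean degree {2*G.l/G.n:.2f}")
print(f"cc_global(primal) = {hm.cc_global(G):.4f}")
print(f"hc_global  = {hm.hc_global(H):.4f}")
print(f"erv_global = {hm.erv_global(H):.4f}")

Hr = hm.rewire_hypergraph(H, hm.RewireConfig(n_operations=20_000, seed=11))
print(f"hc_global(rewired) = {hm.hc_global(Hr):.4f}")

dist = hm.degree_distribution(hm.primal(Hr))
fit = hm.fit_power_law(dist.as_points(), (15, 35))
print(f"tail fit: alpha={fit.alpha:.2f}")
```

Output:

```
primal: 8445 edges, mean degree 14.16
cc_global(primal) = 0.1860
hc_global  = 0.0381
erv_global = 0.0119
hc_global(rewired) = 0.0351
tail fit: alpha=3.61
```

The reading: the primal's global clustering (0.186) is dominated by
the cliques that the abstraction itself manufactures — measured
directly on the hypergraph, where within-reaction co-membership cannot
count as "clustering", the coefficient drops to 0.038 and barely moves
under cardinality-preserving rewiring (0.035). The tail of the rewired
primal's degree distribution still fits a power law, illustrating that
a scale-free-looking tail is compatible with a fully randomized wiring
that merely conserves reaction sizes.

The same pipeline is available from the shell:

```bash
hypermet synth --nodes 1193 --edges 1168 --mean-card 4.19 --seed 7 --out H.json
hypermet convert --mode primal --in H.json --out primal.tsv
hypermet degdist --in primal.tsv --out dist.tsv
hypermet fit --in dist.tsv --region 15 35 --out fit.json
hypermet cluster --in H.json --measure hc-global --out hc.tsv
```

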
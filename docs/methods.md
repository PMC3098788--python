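# Methods

## The model

A metabolic network's connectivity map is represented as a hypergraph
`H = (V, ℰ)`: nodes are metabolite labels (opaque strings — no
chemistry semantics), each hyperedge is a reaction connecting a node
subset of cardinality ≥ 2, and a *directed* hyperedge carries a
bipartition into a non-empty tail (substrates) and non-empty head
(products), with the undirected cardinality `|tail| + |head|`.
Stoichiometric coefficients are not stored — the incidence matrix is
binary, since only incidence structure enters any statistic computed
here — and reaction direction beyond the tail/head split is ignored.
Mass balance, flux constraints and thermodynamics are out of scope.

Two conventions matter downstream:

* **Hyperedge distinctness.** Hyperedges must be pairwise distinct (as
  node sets; as (tail, head) pairs when directed). The one sanctioned
  exception is the enzyme/gene union transform, whose output may
  contain coinciding hyperedges and is flagged accordingly; clustering
  refuses such inputs unless forced, because coinciding hyperedges make
  the intersecting-pair average ill-posed.
* **A species on both sides of a reaction** would violate tail/head
  disjointness. The reaction reader drops it from both sides and logs
  the fact: such species cancel topologically and would otherwise
  create self-loops in the substrate–product abstraction.

## Abstractions

`primal` links every within-hyperedge pair (each reaction becomes a
clique); `cis_primal` and `trans_primal` restrict to same-side and
opposite-side pairs of directed hyperedges; their edge sets partition
the primal's. `plgt` (physical line graph transformation) is the
primal of the dual: the reaction graph in which two reactions are
adjacent iff they share a reactant. All abstractions return simple
graphs and retain the full node set — a node isolated by an
abstraction keeps degree 0 — so per-node frequencies stay comparable
across representations.

The dual is defined by transposing the incidence matrix. A node of
degree < 2 would contribute a dual hyperedge of cardinality < 2; by
default such dual hyperedges are dropped (and logged) rather than
raising, because real networks have leaf metabolites and the reaction
graph must still be computable. Distinct nodes contained in exactly
the same reactions produce coinciding dual hyperedges; the dual is
flagged as duplicate-bearing only when this actually occurs.

## Clustering coefficients

`cc_local` (Watts–Strogatz) and `cc_global` (Barrat–Weigt) are the
classical per-node and 2-path-based coefficients. `cc_global` (and its
hypergraph analogues) are *undefined*, not zero, when no 2-path (no
intersecting hyperedge pair) exists; the error is deliberate, since a
silent 0 would bias ensemble medians at low density.

The hypergraph coefficients are built on the **extra overlap** of two
intersecting hyperedges,

    EO(Ei, Ej) = (|Dij ∩ N(Dji)| + |Dji ∩ N(Dij)|) / (|Dij| + |Dji|),

where `Dij = Ei − Ej` and `N(·)` is the hypergraph neighborhood.
`EO = 0` for identical and for nested pairs (one difference empty).
The neighborhood is computed over the *full* hypergraph, with no
explicit exclusion of `Ei` and `Ej`: exclusion is provably immaterial
because `Dij ∩ Ej = ∅` and `Dji ∩ Ei = ∅` by construction, so neither
hyperedge can close its own overlap. A regression test recomputes EO
with the pair deleted from the neighborhood computation and checks
equality on random instances.

`HC_local(v)` averages EO over the pairs of hyperedges containing `v`
(0 when `v` lies in ≤ 1 hyperedge, mirroring the standard `d(v) = 0`
convention); `HC_global` averages EO over all distinct intersecting
pairs. Both are bounded in `[0, 1]` and reduce *exactly* (machine
precision, verified to 1e-12) to the classical coefficients of the
primal when every hyperedge has cardinality 2.

The **ERV coefficient** is implemented as
`6 × (hyper-triangles) / (ordered 2-path sequences)`, where a
hyper-triangle assigns three pairwise-distinct hyperedges to the three
pairs of a node triple (counted by inclusion–exclusion over the
per-pair covering hyperedge sets) and the numerator equals the number
of closed 3-walks reusing no hyperedge and revisiting no node. The
normalization constant is pinned by the requirement that the measure
reduce to the Barrat–Weigt coefficient on cardinality-2 hypergraphs;
a brute-force walk enumeration confirms the constant on small
instances. Unlike `HC_global`, ERV exceeds 1 on dense hypergraphs of
cardinality ≥ 3, which is precisely why it is kept only as a
comparison measure.

Directed hypergraphs are flattened (tail ∪ head) for all hypergraph
clustering computations; directed variants of `C(k)` are obtained by
abstracting first and applying standard-graph clustering. `C(k)`
averaging uses the arithmetic mean per degree; medians are reserved
for replica ensembles.

## Null models and generators

All generators and rewiring procedures take an integer seed or a
`numpy.random.Generator`; no global state is used, and identical
seed + configuration reproduces output bit-identically.

* `rewire_graph_simple`: remove a uniform edge, link a uniform
  currently-unconnected pair. Conserves (n, ℓ).
* `rewire_graph_degree_preserving`: double-edge swap on two edges
  sharing no endpoint, uniform orientation, rejected on duplicate
  edges. Conserves the full degree sequence.
* `rewire_hypergraph`: remove a uniform hyperedge, resample a uniform
  node set of the same cardinality — tail and head resampled jointly
  (one draw of `|tail| + |head|` nodes, the first `|tail|` becoming
  the tail), the simplest procedure consistent with conserving the two
  side sizes. Conserves node set, hyperedge count and the cardinality
  multiset; replacements colliding with an existing hyperedge are
  rejected and retried.

Rejected attempts do not count toward the operation count
(`RewireConfig.n_operations` counts successful operations), keeping
stated operation counts meaningful; the per-operation retry budget
(default 100) converts pathological density into a clear error rather
than a silent skip.

`gen_fixed_cardinality` draws `m` distinct uniform `k`-subsets
(optionally stopping when the primal reaches a target edge count);
`gen_erdos_renyi` delegates to the exact-edge-count G(n, m) sampler;
`gen_binomial_hypergraph` draws cardinalities as
`2 + Binomial(n_trials, q)` with `q` set so the mean equals
`mean_cardinality`. The defaults — mean 4.19, 8 trials, hence support
2–10 — emulate the reaction-size distribution observed in real
metabolic networks; at the default scale (~10³ nodes, ~10³
hyperedges) the hypergraph is sparse relative to the combinatorial
maximum `C(n, k)`. In directed mode each sampled set is split by a
uniform proper bipartition (rejection on empty sides).

What the generator deliberately does *not* emulate: currency
metabolites (no heavy-tailed node participation), correlated reaction
overlaps (pathway structure), or mass balance. Tests passing on these
synthetic hypergraphs therefore validate the machinery and the
representation-artifact mechanisms, not any biological claim about a
particular organism.

## Degree statistics and power-law fitting

Degree distributions store exact per-degree counts over all nodes
(including degree 0); unobserved degrees are absent rather than stored
as zero rows, since log-log fitting only uses observed degrees.
Ensemble summaries report median and a percentile band (default 5th/
95th) per degree, over the replicas *containing* the degree, and only
for degrees present in at least `min_replicas` (default 10) replicas.

Power-law tails are fit by OLS of `log p(k)` on `log k` (natural log;
the base cancels in α), never by maximum likelihood — matching the
procedure used throughout the metabolic-network literature this
toolkit is meant to interrogate. Zero frequencies inside the region
are dropped with a warning.

The automatic fitting region comes from two rules applied to an
ensemble summary. *End*: scanning degrees upward, the region ends at
the last degree before the chosen percentile first fails to exceed the
single-node frequency floor `1/n` (frequencies are fractions of `n`,
so the floor is well defined; below it a log-log plot carries no
signal). Two strategies are provided, comparing the upper percentile
(default) or the lower one (equivalent to requiring that almost all
replicas have more than one node at the degree) — the literature's
phrasing of this rule is ambiguous, so both readings are exposed and a
manual region is always accepted, which is also the right choice for
single observed networks. *Start*: moving from the end toward degree
1, the region starts at the first pair of neighboring degrees whose
log-log median slope magnitude drops below `slope_threshold` (default
4.0), marking the crossover from the zig-zag head to the tail; if no
pair is that flat, the region extends to the smallest reported degree.

`degree_mod_classes` partitions observed degrees into residue classes
mod (k − 1): each cardinality-k hyperedge contributes k − 1 to a
member's primal degree, so sparse hypergraphs overpopulate multiples
of k − 1 (the zig-zag head), and the classes decompose the
distribution into smooth strands.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run the ensemble
experiments at reduced scale, chosen to preserve the qualitative
regimes (sparsity, mean degree) of the full-scale setting:

* Binomial-vs-ensemble medians and the zig-zag head: 100 replicas of
  the fixed-cardinality generator at n = 300, m = 290 (same m ≈ n
  sparsity as 1193/1168), k = 2 and 3. Agreement with the
  `Binomial(n−1, m/C(n,2))` closed form is required to within 0.02
  absolute on median frequencies (≈ 6 standard errors of a median over
  100 replicas at the modal degree).
* Clustering-vs-density comparison grid: 30-node hypergraphs (the
  scale used for this comparison in the literature), cardinalities
  2–5, hyperedge counts m ∈ {30, 60, 120, 240}, 5 replicas per point,
  median aggregation. A hyperedge-count grid replaces an inclusion-
  probability grid because `p·C(30,5)` hyperedges is computationally
  out of proportion at high p.
* Sparse Erdős–Rényi `C(k)` scaling: 20 replicas at n = 1193,
  ℓ = 5719; the exclude-zero `C(k)` curve is fit over the manual
  standard-graph region [5, 13]. Above k ≈ 13 the curve departs from
  `γ_k` because a second neighbor edge becomes likely, so the minimal-
  curve regime is the low-to-mid degree window.
* Null-model contrast: directed hypergraphs with cardinality-4
  hyperedges split 2/2 (150 nodes, 140 hyperedges, 3000 operations,
  15 replicas). The constant cardinality gives a clean mod-(k−1)
  contrast — `Z = min(p(2), p(4)) − p(3)` is positive when the
  hypergraph is rewired and the abstraction taken afterwards, and
  negative when the abstracted graph is rewired directly; mixed
  binomial cardinalities blur the residue classes at this scale.
* Conservation checks: 10⁴ operations per rewiring procedure.
* Oracle equivalence: exhaustive enumeration over all 2951 hypergraphs
  with 5 nodes and ≤ 3 hyperedges (extra-overlap axioms), plus 100
  random hypergraphs with ≤ 8 nodes against brute-force
  implementations of `HC_local`, `HC_global` and the ERV walk count.

## Known limitations

* The hypergraph clustering computations are exact, not sampled; on
  very dense hypergraphs (node degrees in the hundreds) the
  intersecting-pair enumeration grows quadratically in degree.
* The ERV triangle count enumerates covered node triples; it is
  intended for the comparison experiments, not for massive dense
  hypergraphs.
* `read_reactions` parses the documented 4-column TSV dialect only;
  extracting that TSV from a database dump (KEGG, SBML, BiGG) is out
  of scope.
* Rewiring is a fixed number of operations, not a mixing-diagnosed
  Markov chain; operation counts in the hundreds of thousands are the
  caller's responsibility where convergence matters.
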
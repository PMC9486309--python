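# Methods

`modulink` implements a three-stage computational chain for extending a
curated disease gene set: over-representation analysis of the gene set
against pathway annotations, construction of a pathway-crosstalk network
from the enriched pathways, and prioritization of novel candidate genes in
a protein interactome by seed-pair shortest-path betweenness with a
permutation FDR. A synthetic-study generator with planted ground truth
makes every stage testable offline.

## Over-representation analysis

For a query set drawn from a background universe of N genes, a pathway with
K genes in the background, a query of n genes, and an observed overlap of
k, the enrichment p-value is the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

identical to a one-sided Fisher exact test on the 2x2 overlap table.
Over-representation is the only direction tested. The tail is computed with
exact integer combinatorics (`math.comb` plus a single rational-to-float
rounding), so it agrees with exhaustive enumeration to full float precision;
`scipy.stats.hypergeom.sf` serves as an independent cross-check in the test
suite. Multiple testing uses the Benjamini–Hochberg step-up procedure
(delegated to `statsmodels`), applied within one annotation collection at a
time, and only over the pathways actually tested: pathways sharing fewer
than `min_observed` (default 2) genes with the query are dropped *before*
correction. The default background is the union of all annotation members —
the standard reproducible-offline convention when no explicit universe is
given; a user-supplied background is accepted, and query genes outside the
background are dropped with a log message. Significance is `p_BH < alpha`
(default 0.05), optionally also requiring the raw p below alpha
(`require_raw_p`) for users who want the stricter joint rule.

Annotations are flat GMT gene sets; no ontology-graph propagation is
performed.

## Pathway crosstalk

Two significant pathways crosstalk when they share at least `min_shared`
(default 2) candidate genes. Each retained pair is scored by

    JC = |A ∩ B| / |A ∪ B|,   OC = |A ∩ B| / min(|A|, |B|),
    score = (JC + OC) / 2,

where A, B default to the pathways' *observed candidate* sets
(query ∩ pathway); full database memberships can be supplied instead via
`membership` — the choice of operand sets is genuinely ambiguous in
practice, so both modes exist and neither is asserted against published
score tables. The network is pruned to the top fraction of edges (default
50%) using a ceiling rule — `ceil(fraction · n)` edges — with all edges
tying the cutoff score retained, which makes the selection deterministic
and order-independent. Note the tie-retention rule means re-applying the
selection to its own output can shrink it further when scores are distinct;
the operation is deterministic and monotone in `fraction`, but not
literally idempotent.

Modules are detected by weighted greedy modularity maximization
(`networkx`), with the crosstalk score as edge weight, rather than by
connected components: a single connector pathway joining two modules would
merge them as components, while modularity keeps them apart and lets the
connector be flagged. Nodes whose neighbors span two or more modules are
flagged as bridges. Determinism comes from sorted node insertion and
labeling communities by their smallest member. Exports are SIF and GraphML
(Cytoscape-compatible), with JC/OC/score/shared-count edge attributes and
module labels as node attributes.

## Interactome prioritization

For seed genes S in an undirected, unweighted, simple interactome, each
gene v receives

    B(v) = Σ_{ {s,t} ⊆ S } σ_st(v),

the number of geodesics (hop-count shortest paths) between unordered seed
pairs on which v is an interior node, computed with the geodesic-counting
identity σ_st(v) = σ_sv · σ_vt when d(s,v) + d(v,t) = d(s,t). All geodesics
per pair are counted (equivalent to K-shortest paths with unbounded K
restricted to minimal length — parameter-free); unordered pairs are used
(ordered counting would double every value and leave any selection
invariant at a doubled cutoff); disconnected pairs contribute nothing;
seeds are not excluded from scoring as interior nodes of *other* pairs'
geodesics, so seeds can reappear among candidates. The kernel is a
level-synchronous BFS over a CSR adjacency matrix with per-pair vectorized
accumulation; path counts are held in float64, exact below 2^53. A
brute-force enumeration of all geodesics (`networkx all_shortest_paths`)
is the oracle in the tests.

Raw betweenness partly reflects topology: cut vertices and hubs score high
for any seed placement. A permutation null controls for this: R (default
100) replicates redraw |S| seeds uniformly at random from all nodes
(a degree-weighted mode is available but not default) and recompute B.
Per gene,

    FDR_i = #(B_null > B_actual) / R        (strict inequality),

which lies on the grid {0, 1/R, …, 1}. Candidates are retained when
`B_actual > b_min` (default 1000, appropriate for interactome-scale
networks; synthetic studies use a percentile cutoff instead, because
absolute path counts scale with the number of seed pairs and graph size),
`FDR < fdr_max` (default 0.05), and a hub statistic below `hub_max`
(default 50). All comparisons are strict.

The hub statistic defaults to the **mean null betweenness** — the expected
number of random shortest paths through the gene, directly in units of
path counts. This is the discriminating quantity: topological hubs carry
thousands of random-seed paths, planted or disease-module linkers almost
none. The alternative statistic, the count of replicates with any nonzero
null betweenness (`positive_count`), is offered as an option but is heavily
degree-confounded: on graphs of a few thousand nodes, most mid-degree nodes
lie on *some* random-pair geodesic in more than half the replicates, so it
rejects far more than true hubs; with 60 seeds attaching to 20 linkers the
planted linkers unavoidably reach degree ≈ 9 and would be rejected almost
uniformly under that statistic.

Reproducibility: one integer master seed; replicate r uses a stream derived
from `SeedSequence(master, spawn_key=(r,))`, so the null is bit-identical
across runs and independent of evaluation order.

## Synthetic studies

The generator emulates the pipeline's three inputs with known truth:

* **Interactome** — a Barabási–Albert preferential-attachment graph
  (default 2000 nodes, m = 3): the heavy-tailed degree distribution is what
  makes hub exclusion meaningful. An Erdős–Rényi mode (density-matched,
  components stitched deterministically) exists for null experiments.
* **Planted module** — `n_linkers` (default 20) linkers are drawn from the
  lowest-degree background nodes (hidden linkers are ordinary genes, not
  hubs; making them hubs would confound the planted signal with exactly the
  background effect the permutation null removes). `n_seeds` (default 60)
  *new* nodes attach only to linkers, `linker_attach` (default 2) each. The
  first `n_linkers` seeds form a cycle over the linkers, which guarantees
  the planted module is connected and every linker is shared by at least
  two seeds — hence lies on a length-2 seed-to-seed geodesic (the planted
  truth invariant). Remaining seeds pick linkers at random. A `dilution`
  mode additionally wires seeds into the background for harder recovery
  problems. No linker–linker edges are added: wiring scattered peripheral
  nodes together creates long-range shortcuts that would make the linkers
  transit hubs under the null.
* **Annotations** — `n_pathways` (default 30) gene sets of sizes 10–40
  drawn from the node universe. A fraction (default 0.3) is enriched: those
  receive `enrichment_boost` (default 6) forced seed genes, with the rest
  of their members drawn from non-seed genes so the excess over the
  hypergeometric expectation has known size. Consecutive pathway pairs
  share `overlap_rate` (default 3) forced genes so the crosstalk stage has
  signal; a disjoint mode partitions the universe instead.

All generator randomness flows from the master seed through named child
streams.

What the generator does *not* emulate: the size and exact degree sequence
of a real interactome (13k+ nodes), literature-curation noise in seed
lists, annotation redundancy structure (ontology hierarchies), or
assortativity/clustering of real protein networks. Passing recovery tests
therefore demonstrate the machinery's correctness and discriminative power
under scale-free topology with a planted module, not field performance on
any specific real interactome.

## Benchmarks and problem sizes

The recovery benchmark runs the full prioritization on the default desk
configuration (2060-node graph, 60 seeds, 100 permutations), with the
betweenness cutoff at the 99th percentile of the actual betweenness
distribution, FDR < 0.05 and mean-null < 50. Precision and recall for the
planted linkers are computed over non-seed candidates (seeds are known
inputs, not discoveries) and averaged over 10 generator seeds; typical
values are precision ≈ 1.0 and recall ≈ 0.8–0.9. Null calibration redraws
the seed set uniformly at random (no planting) and measures the flagged
fraction at the same thresholds (typically ≲ 0.1%, bounded by the
percentile cutoff itself). These problem sizes keep a full benchmark run in
the low minutes on one CPU while leaving hundreds of nodes between the
planted module and the background distribution.

## Numerical and degenerate-input choices

* Symbol normalization is uppercase + strip only; no alias or cross-ID
  mapping (an optional user alias table is applied pre-normalization).
* Tail probabilities are exact rationals rounded once to float.
* Edge identity uses lexicographically ordered pathway-id pairs; undirected
  interactome edges are deduplicated including reversed duplicates, and
  self-loops are dropped with counts logged.
* `n_perm = 0` is legal: prioritization then filters on betweenness only
  and leaves the FDR column empty, with a warning.
* Empty enrichment results, empty candidate tables, and all-tied score
  lists are legal outputs; empty *inputs* (no valid symbols, no edges,
  edgeless networks) are validation errors that name the offending file
  and line.

## Packaged fixtures

The package ships plain-text transcriptions of a published worked example:
a 176-gene curated disease gene set, 24 enriched pathways with their
candidate-gene members (GMT), and a 42-row candidate table with printed
betweenness values. Two members of the gene set (ABCA1, KERA) are restored
from the pathway-membership table of the same source, where some renderings
of the gene table omit them; the fixture header documents this. A published
crosstalk-score table is also shipped, marked non-authoritative (the
published rendering is visibly misaligned); it is never used in
computation. Published enrichment p-values and betweenness values depend on
2020-era annotation databases and a proprietary interactome snapshot and
are deliberately not recomputed; the oracle and recovery suites take their
place.
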
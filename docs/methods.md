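# Methods

`netcompare` compares 2–8 undirected networks that share a node
namespace. This note records the models and conventions behind each
analysis, the parameters that matter, what the synthetic generators do
and do not emulate, and the design choices made where more than one
reasonable convention exists.

## Input model

Networks arrive as delimited edge lists with 1-based source/target
(and optional weight) columns. Edges are undirected: every pair is
stored with its endpoints in lexicographic order, so `A B` and `B A`
are one edge. The undirected reading is deliberate — modularity
agglomeration, clique enumeration and edge-Jaccard overlap all assume
symmetric adjacency, and the source/target columns of typical
association-network exports are a serialization convention, not a
direction. Duplicate edges collapse to one; when duplicate weights
conflict, the last one read wins and a warning is logged. Self-loops
are dropped by default (they have no meaning for cliques or
communities and distort clustering coefficients) but can be retained
with a flag. Node identifiers are compared case-sensitively and
whitespace-trimmed only; no other normalization is applied, because a
gene symbol and its lowercase variant may be genuinely different
tokens in a user's namespace. Blank lines and `#`-prefixed lines are
skipped. Collections hold at most 8 networks — the pairwise and
exact-subset computations grow as 2^k in the network count, and 8
keeps every region enumerable (255 subsets) while covering typical
multi-condition designs.

## Global and local properties

The global preview reports total nodes, total edges, **cluster
coefficient** and **density**. "Cluster coefficient" here is the
*average local* clustering coefficient, with nodes of degree < 2
contributing 0 — the common preview statistic; the triangle-ratio
transitivity is exposed separately under its own name since the two
are frequently conflated.

Local measures: degree, betweenness, HITS hub/authority, eccentricity,
eigenvector centrality, closeness, coreness.

* **Betweenness** defaults to raw pair counts (a node on the single
  shortest path of one pair scores 1). Comparisons across networks of
  similar size read the same either way; the normalized variant sits
  behind a flag.
* **Eccentricity** is computed within each node's connected component
  rather than erroring or reporting infinity on disconnected graphs —
  every node gets a value, which is what a comparison table needs.
* **Eigenvector centrality** uses power iteration (uniform start,
  tolerance 1e-8, max 1000 iterations — no randomness) and is rescaled
  to unit maximum per network, as are the HITS scores, so values are
  comparable across networks of different sizes.
* **HITS** on an undirected graph has hub = authority: both equations
  share the nonnegative Perron vector of the adjacency matrix as their
  fixed point. The implementation therefore power-iterates the shifted
  operator A + I directly (same Perron vector, strictly dominant
  eigenvalue). This sidesteps two numerical traps: the alternating
  hub/authority update oscillates between the two sides of bipartite
  components, and SVD-based eigensolvers return per-component signs
  arbitrarily on disconnected graphs.
* **Coreness and closeness** are included because property-mapped
  network views customarily size nodes by degree, betweenness or
  coreness.

Cross-network ("delta") tables put one node per row and one network
per column, ordered by descending value in the first network. A node
missing from a network is recorded as an explicit ABSENT marker (`NA`
in TSV), never 0 — absence and isolation are different observations.

## Set comparison

For a selection of networks, every element of the union (nodes or
edges; edge identity ignores weights) maps to the exact subset of
networks containing it. Region counts are therefore **exclusive**
(standard UpSet semantics): the region {1,2} holds elements in
networks 1 and 2 *and no other*. Regions are pairwise disjoint, cover
the union, and reconstruct each network's element set as the union of
regions containing its label — these three identities are enforced by
property tests. An inclusive "shared by at least these networks" view
is derivable and exposed as a query. UpSet rows sort by region size
(set cardinality) or subset size (combination cardinality), ties
broken lexicographically; Venn output is sensible up to 5 sets, UpSet
rows have no such limit. The derived graphs follow set algebra:
intersection (edges in all selected networks), exclusives (edges in
exactly one), and the union graph annotated with per-node and per-edge
membership sets — the data behind pie-chart node coloring.

## Similarity and dendrogram

Network similarity is the Jaccard index of edge sets. Two empty edge
sets count as identical (s = 1); this degenerate case is logged.
Clustering runs on the distance d = 1 − s with **average linkage**
(UPGMA), the common default for similarity dendrograms; the merge
height recorded for a join is the average pairwise leaf distance, so
two networks merge exactly at 1 − s. Equal candidate distances break
ties by the lexicographically smallest pair of cluster
representatives, making the tree fully deterministic; a test
cross-checks all merge heights against scipy's average-linkage
implementation on random matrices. Newick serialization assigns each
branch the difference between parent and child merge heights, giving
an ultrametric tree. Distances from the global union are reported as
1 − Jaccard so that "equal to the union" reads 0 on the radar axes —
the distance semantics the chart implies.

## Shortest paths

All co-optimal paths between source and target are enumerated per
network (BFS predecessor-DAG reconstruction for unit weights; plain
single-path Dijkstra cannot produce the co-optimal set), ordered
lexicographically by node sequence. Unweighted hop counts are the
default — condition comparisons are naturally phrased in hop counts
(a direct interaction becoming a two-step detour, for example) — with
a weighted Dijkstra mode behind a flag
that requires positive weights. Order numbers assign the source 0 and
each subsequent node its position, so the target's number is the path
length. Preferred-node counts tally, per intermediate node, the number
of selected networks whose shortest paths contain it — once per
network regardless of how many co-optimal paths within that network
use it, and excluding source and target, which trivially appear on
every path. A disconnected pair in one network produces no records for
that network (logged, not an error); only a pair absent from every
selected network is an error.

## Communities and transitions

Partitions come from Clauset–Newman–Moore greedy modularity
agglomeration: start from singletons, repeatedly merge the community
pair with the largest modularity gain, cut at maximum Q (standard
unweighted modularity; weighted modularity is out of scope). Runs are
seedless and deterministic. Isolated nodes become singleton
communities; an edgeless network yields all singletons with Q = 0 and
a warning. Communities are ordered by descending size with ties broken
by lexicographically smallest member, and the reported Q is re-derived
from the returned partition, which tests compare against the direct
formula at 1e-12.

Transition scoring between partitions A and B computes, for **all**
|A| × |B| cross pairs, the node-set Jaccard score and intersection
count. The summary scores are sum_jaccard = Σ pairwise Jaccard and
weighted_sum_jaccard = sum_jaccard / (|A|·|B|) × 100. The all-pairs
denominator is the literal reading of "total comparisons made" and
reproduces the small magnitudes (units, not tens) that many-community
partitions produce; a variant dividing only by the overlapping-pair
count is reported alongside for sensitivity. Nodes present in one
network only count against the union of every pair involving their
community — departures are real transitions, not noise to be masked.
Lower weighted scores mean stronger reshuffling by construction.

Rank embeddings pool the per-node degree, hub and betweenness values
of both networks into one observation list (a node in both networks
contributes twice), rank ascending with average ranks on ties, and
divide by the pooled count — so a unique pooled maximum maps to 1.0.
Pooling, rather than per-network ranking, is what makes the two
heatmap strips of a transition diagram comparable; rank (rather than
min–max) normalization is robust to the heavy-tailed score
distributions centralities produce.

## Cliques

Maximal cliques are enumerated with Bron–Kerbosch pivoting. "Cliques
of size ≥ k" means **maximal** cliques of size ≥ k — reporting every
complete subgraph would bury each K_m under its 2^m subsets. Default
k = 3, since dyads are simply edges. Output order is descending size,
then lexicographic members. Tracking projects a clique onto another
network: members present, members absent, and the count of the
C(s, 2) clique edges that survive there.

## Synthetic networks

* `generate_random` draws uniform G(n, m) graphs — exact edge counts,
  matching benchmark categories defined by (n, 2n–5n edges) with
  replicates that share shape but not wiring. G(n, m) rather than
  G(n, p) because the categories fix m exactly.
* `generate_family` emulates condition-to-condition rewiring: each
  derived network keeps a fraction `overlap` of the base edges and
  rewires the rest outside the base edge set. Measured edge-Jaccard to
  the base is monotone in the requested overlap (tested).
* `generate_planted_partition` produces two-block graphs
  (default 2×20 nodes, p_in = 0.9, p_out = 0.02) with ground-truth
  labels for recovery tests.

Node labels `N000001…` sort lexicographically in generation order, so
downstream tie-breaks are reproducible. All randomness flows from the
explicit per-call seed; there is no global RNG state.

What the generators do **not** emulate: degree heterogeneity
(scale-free tails), weighted association strengths, correlated noise
between conditions, or the compositional artifacts of real abundance
data. Passing tests on these fixtures therefore demonstrate
*algorithmic correctness* — set identities, oracle agreement, planted
recovery — not robustness to the statistical pathologies of inferred
biological networks, which enter upstream of this tool.

## Verification strategy and problem sizes

Every non-trivial computation is checked against an independent route:
exhaustive subset enumeration for maximal cliques (≤ 15 nodes),
exhaustive simple-path search for shortest-path sets (≤ 12 nodes),
brute-force pair enumeration for betweenness (≤ 12 nodes), exhaustive
set-partition search for maximum modularity (≤ 8 nodes), direct
formula evaluation for Q, set algebra replayed per element for
regions, and scipy average linkage for dendrogram heights. Property
tests cover the partition/cover identities on batches of random
collections (100 collections of 3–5 networks), metric behavior of the
Jaccard distance (1000 random triples), planted-partition recovery
(≥ 95 of 100 seeds), and a functional end-to-end pass over the largest
benchmark category (5000 nodes / 25,000 edges: global properties, all
eight local measures, communities, cliques — a few minutes on one
CPU). These sizes keep the oracles exact and the full suite fast while
exercising every code path at the scale the tool targets (networks of
hundreds to a few thousand nodes).

## Known limitations

* Directed and multigraph semantics are out of scope by design.
* Weighted modularity and weighted Jaccard overlap are not
  implemented; weights participate only in Dijkstra path costs.
* CNM greedy agglomeration is a heuristic: its Q can fall below the
  true maximum on adversarial graphs (tests only require it never to
  exceed the brute-force optimum and to recover well-separated planted
  structure).
* The 8-network cap is architectural (2^k exact regions); larger
  batches need a different region representation.
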
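# Methods

## Scope and model

nettopo analyses undirected simple graphs over string-labelled nodes. All
inputs — directed curation tables included — are coerced to undirected
topology: an interaction row (source, relation, target) contributes one
unordered edge, and the relation label is carried as annotation only. Node
identity is the exact label after trimming leading/trailing whitespace, with
no case folding: biological labels distinguish species by case and
punctuation ("F-actin" vs "actin", "[Ca2+]i"), and silent case-merging could
fuse distinct molecules. (Overlap analysis across *networks* is the one place
case-insensitive matching is the default, because independent curations
routinely print the same molecule as "ACTIN"/"Actin"; it is switchable.)

Cleaning is an explicit, idempotent step: readers preserve the raw edge
multiset (self-loops and duplicate lines included) so curation artefacts can
be audited, and `clean_network` collapses it to a simple graph. Nodes
isolated by loop removal or stoplist filtering are kept by default — they
still count as molecules in the node tally — with a flag to drop them, since
upstream tools differ on this and the choice changes reported node counts.
Stoplist matching is exact-label, never substring (filtering "membrane" must
not remove "membrane receptor"); every removal and ignored term is logged.

## Topological parameters

All metrics are computed from their definitions (no delegation to a graph
library's summary routines), so each convention is explicit:

- **Clustering.** C_I = 2 n_I / (k_I (k_I − 1)), with n_I the number of edges
  among the k_I neighbours of node I. For k_I < 2 the coefficient is
  undefined and the node is excluded from the network mean by default; the
  alternative convention (counting such nodes as 0) is available via flag.
  The default matters: on sparse networks the two conventions differ
  substantially, and published tables rarely state which was used.
- **Shortest paths.** Breadth-first search from every node; accounting is
  over ORDERED pairs (n, m), n ≠ m, so a connected N-node network has
  N(N−1) finite pairs and the coverage percentage has denominator N(N−1).
  This ordered-pair convention reproduces the printed pair counts of the
  network-analysis GUIs this workflow is modelled on (e.g. 16256 = 128·127).
  The characteristic path length is the mean over finite pairs only; the
  diameter is the largest finite distance (undefined when no pair is
  connected).
- **Degree distribution.** Node counts per degree class; degree-0 nodes are
  tallied separately because log k is undefined downstream.
- Serialized rows round to 3 decimals; internal values are full precision.

## Power-law fitting

Fits are ordinary least squares of log10 y on log10 x — the simple
logarithmized-data fit, not maximum-likelihood estimation — because the
analysis this package reproduces is the least-squares one and the two
estimators answer different questions. Two goodness statistics are reported
and are deliberately distinct:

- **R²** — coefficient of determination of the linear fit on logarithmized
  data (identically the squared Pearson correlation of the log-log points);
- **r** — Pearson correlation between observed values and fitted power-law
  values on the original scale.

Printed result tables in this field routinely show r² ≠ R², which only makes
sense if the two statistics live on different scales; the pair of
definitions above (the NetworkAnalyzer convention) reproduces that
behaviour. Zero counts and zero-clustering degree classes are excluded
(logged) rather than offset-shifted; degrees are fitted as raw classes, with
no logarithmic binning. The degree–clustering fit uses per-degree-class mean
clustering by default (per-node scatter via flag). Fits fail loudly (a
`FitError`) below 2 usable points or when all x coincide; on noiseless
power-law input the exponent and amplitude are recovered to ≈1e−15.

When either side of the original-scale correlation has zero variance the
Pearson r is undefined; we report 1.0 when the fit reproduces the data
exactly (the two-point case) and 0.0 otherwise.

## Hubs and classification

Hubs: degree ≥ mean + 1 standard deviation. The SD is the population
(divide-by-N) one, because the node set is the entire population rather than
a sample; sample SD is a flag. "At least one SD above" is read inclusively
(≥). When all degrees are equal the threshold equals the common degree, every
node qualifies, and the result is flagged degenerate.

The classifier is a pure function of an evidence tuple (degree-fit γ and R²,
mean clustering, degree–clustering r, CPL, mean degree, reachability):

- **hierarchical** if mean clustering ≥ 0.3 AND |r| of the C(k) fit ≥ 0.5;
- **scale_free_BA** if degree-fit γ < 0 AND R² ≥ 0.5 AND mean clustering
  < 0.3;
- otherwise **indeterminate** (including any fit failure).

Mean clustering is the load-bearing separator: observed curated/pathway/BA
networks cluster at 0.017–0.073 while text-mined ones sit at 0.55–0.66, so
0.3 splits the regimes with wide margin on both sides. The |r| condition is
conjunctive because low-clustering networks can show moderately high C(k)
correlation by chance; |r| alone cannot classify. All cut-offs are exposed
in `ClassifierConfig`, not hard-coded, since no canonical numeric definition
of "uncorrelated with the clustering coefficient" exists.

Small-world annotation: CPL ≤ 1.5·ln N / ln⟨k⟩ with ≥ 90% ordered-pair
reachability. This is an interpretation of the usual qualitative claim
(short paths at modest mean degree), documented as such, and feeds no
classification decision.

## Synthetic generators

The generators stand in for real curated edge lists and define the
conditions the tests and acceptance script run under:

- **Barabási–Albert** (N = 128, m = 2 as the reference configuration): seed
  graph K_{m+1}; each new node attaches to m DISTINCT existing nodes drawn
  preferentially by degree without replacement. Edge count is exactly
  C(m+1,2) + (N−m−1)·m = 253 at the reference size; the graph is connected
  with minimum degree m. Under this convention mean clustering at N=128,
  m=2 is ≈ 0.09–0.10 — a little above the ≈ 0.02–0.07 seen in sparse
  empirical scale-free networks of this size, because the clique seed and
  distinct-target rule both promote triangles; this does not affect
  classification (cut at 0.3). A randomizer variant that yields a
  disconnected graph with ~196 edges at these parameters exists in the
  wild; its exact growth rule is undocumented, so the canonical model above
  is used and the two-component shape is provided separately
  (`two_component`: a BA main part plus a disjoint triangle, giving the
  125 + 3 decomposition).
- **Hierarchical**: Ravasz-style deterministic construction — a 5-clique
  module; at each further level four peripheral copies of the previous
  level are attached and all their peripheral nodes are wired to the root
  hub (5^levels nodes; levels ≤ 4 as a size guard). Mean clustering stays
  ≈ 0.8 (above the 0.55–0.66 of text-mined networks, but safely in the
  high-clustering regime) and C(k) decreases with k, which is what the
  classifier's second branch needs. An optional seeded rewiring of 2% of
  edges adds disorder without leaving the regime.
- **Erdős–Rényi** G(N, p) as the unstructured control, plus deterministic
  star/ring/complete/two-component fixtures.

All stochastic draws come from one explicitly seeded `numpy` generator; the
same config yields byte-identical serialized files.

What the synthetic regimes do NOT emulate: the long-tailed curation noise of
real literature mining (ambiguous aliases, paper-specific labels), directed
or signed interactions, and edge multiplicity by evidence type. Passing
regime-recovery tests therefore shows the pipeline separates the two
architectures when they are present; it does not validate any specific
biological curation.

## Numerical and design choices

- Log base 10 throughout the fits (slope and R² are base-invariant; the
  amplitude is the base-10 intercept back-transform).
- Component ordering is by size descending with ties broken by the
  lexicographically smallest member label, so outputs are deterministic.
- Venn partitions are exact membership-vector partitions over 1–5 named
  sets (the practical ceiling for a readable diagram); region counts sum to
  the union size and satisfy inclusion–exclusion by construction.
- `run_comparison` records per-network fit failures instead of aborting,
  and omits overlap maps (with a log note) beyond five networks.
- Problem sizes in tests and the acceptance script: oracle equivalence on
  100 random graphs of ≤ 30 nodes (exhaustive triangle enumeration and
  Floyd–Warshall are exact there), regime recovery on 50 seeds each of
  BA(128, 2) and the level-3 hierarchical construction — the reference
  network scale of the study design.

## Known limitations

- SIF node labels containing whitespace cannot round-trip (the format is
  whitespace-delimited); edge-list TSV handles them.
- The original-scale r of a power-law fit is unstable when only a handful of
  degree classes are usable (typical for sparse ER controls): per-seed |r|
  fluctuates widely even though the median sits well below the hierarchical
  regime. The classifier is robust to this because the clustering condition
  gates the hierarchical branch.
- Classification cut-offs are calibrated to the two observed regimes; a
  network genuinely between regimes (clustering ≈ 0.1–0.3) will come out
  indeterminate rather than forced into a class.
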
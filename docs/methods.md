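# Methods

This note documents the model implemented by `nasfinder`, the parameters
that matter, the numerical conventions, and what the synthetic validation
does and does not establish.

## Model and assumptions

The method treats a cell's molecular state change as information flowing
through an interactome from upstream regulator molecules (receptors,
transcription factors or transporters) to the differentially expressed
genes that record the response. Three assumptions follow:

* **Undirected traversal.** All interactions are treated as symmetric
  channels; any direction column in input files is ignored. This trades
  signaling-direction fidelity for applicability to interactomes without
  curated directionality.
* **Shared neighborhood as interaction strength.** The common linkage
  index CL<sub>ij</sub> = (D<sub>ij</sub> + I<sub>ij</sub>)/(n<sub>i</sub> + n<sub>j</sub>)
  scores an edge by the proportion of shared neighbors relative to the two
  endpoints' total neighbors (D<sub>ij</sub> adjacency indicator,
  I<sub>ij</sub> common-neighbor count, n<sub>k</sub> degree). Non-adjacent
  pairs score 0. On any edge each common neighbor adds 1 to the numerator
  but 2 to the denominator, so CL ∈ (0, ½] in this form; products over
  paths therefore decay strictly with length, and multiplicative path
  scores favor short, densely embedded routes.
* **Gene-level tissue context.** Tissue specificity is a property of genes
  (TE/GE/TEn classes), so pruning removes genes and their incident edges,
  never edges alone.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `regulator_role` | `receptor` | molecular role of the upstream anchors |
| `max_path_len` | 9 edges | cap on retained path length |
| `distance_cap` | 10 hops | genes at distance ≥ 10 from every regulator are considered unreachable (must exceed `max_path_len`) |
| `extend_1neighbor` | true | add every neighbor of a path node to the sub-network |
| `alpha` | 0.05 | significance threshold used by the benchmark confusion counts |
| `universe` | collection size | hypergeometric universe N |
| `similarity` | `dice` | cross-sub-network selection criterion (`neglogp` alternative) |
| `regulator_scope` | `per_gene` | each module gene nominates its nearest regulators (`module_global` keeps only the module-wide minimum) |

The 9-edge cap reflects that long interactome paths are rare and carry
little evidence; it also bounds the layered dynamic program, which runs in
O(`max_path_len` × |E|) per regulator.

## Numerical and procedural choices

* **Max-product search.** Implemented as a hop-layered relaxation over
  walks. Because every edge weight is strictly below 1, removing a cycle
  strictly increases a walk's score, so the optimum is always a simple
  path. Ties break toward higher score, then fewer edges, then the
  lexicographically smallest node sequence — making the retained path, and
  every downstream table, deterministic. Scores are accumulated
  left-to-right so they are bit-identical to a naive enumeration.
* **Per-gene regulator nomination.** "Closest" is resolved per module
  gene, then unioned: a single module-wide minimum would leave genes in
  distant network regions without a regulator. All regulators tied at a
  gene's minimal distance are kept. The module-global variant remains
  available via `regulator_scope`.
* **Enrichment selection order.** Per sub-network the reference set with
  the lowest hypergeometric p is kept (ties: larger Dice, then name
  order); per regulator, the candidate sub-network with the largest Dice
  is marked selected (ties: larger NAS). Dice is used as "the" similarity
  score; `similarity="neglogp"` switches the cross-sub-network criterion.
* **NAS conventions.** The overlap CDR is taken against the
  network-restricted target set *T*, keeping the activity score consistent
  with the enrichment target (`cdr_scope="module"` scores against the full
  DEG list instead). Min–max extremes v_min/v_max are taken with sign over
  all DEGs of the comparison — across modules — so NAS values of one
  contrast are comparable; the asymmetric scaling deliberately weights
  up-regulation (activation) above down-regulation. Degenerate input with
  all fold changes equal maps every gene to 0.5 (neutral) with a warning
  rather than failing.
* **Hypergeometric universe.** Defaults to the number of distinct genes in
  the loaded pathway collection. The p-values only rank candidates, so any
  consistent universe yields the same selections; the value is
  configurable for users who prefer a genome-wide N.
* **Functional-group filter.** Incoming annotation clusters are scored
  with −log10 of the geometric mean of their term p-values (the standard
  enrichment-score definition, under which a group of p = 0.05 terms
  scores ≈ 1.3); groups scoring > 1 are kept and only genes from terms
  with p < 0.05 enter a DEG module.
* **Benchmark windows.** Pathways ranked outside a top-k window (or absent
  from a tool's output) are treated as not called — counted as false
  negatives if labelled positive, true negatives if negative. This is the
  only convention under which the top-10/top-100 windows differ from
  "all". z-scores use the sample (n−1) standard deviation across tools,
  the conventional choice at small tool counts; zero cross-tool variance
  yields z = 0.
* **Per-length path champions.** `retention="per_length"` merges one
  champion path per hop count instead of the single best path per gene.
  Champions at non-optimal lengths come from the same per-node dominance
  relaxation and are a deterministic heuristic there (the overall best
  path is always exact); non-simple walks are discarded.

## Synthetic data: what it emulates and what it does not

`synthdata` builds a modular interactome: preferential-attachment
communities (heterogeneous degrees, locally dense — the texture of
signaling networks) joined in a path by linker chains of 8 nodes. A bridge
therefore costs 9 edges, so under the default path cap a regulator's
sub-network stays community-local while neighboring communities remain
partially reachable — emulating the locality of signaling neighborhoods in
a large interactome at a desk-scale node count (240 nodes, 420 edges, 8
communities by default; simulations in the test suite use these sizes).

Each community contributes one receptor-anchored cluster of 8 non-receptor
genes (pairwise disjoint across communities) that doubles as a reference
pathway; the DEG module is the union of all clusters. One uniformly chosen
cluster is planted: its genes draw log2 fold changes from
`planted_effect + N(0, noise_sd)` (defaults 2.0 and 0.1 — a strong,
low-noise 4-fold response), decoys from `N(0, noise_sd)`. Because the
planted label is exchangeable with the decoys, a zero-effect run provides
an exact null: the planted cluster should win the NAS ranking in ≈ 1/K of
seeds, and the recovery test's complement (planted effect present, planted
pathway ranked first) isolates the contribution of the expression signal.

What passing these tests shows: the pipeline's plumbing is correct
end-to-end and the NAS ranking responds to planted expression signal, not
to structural artifacts. What it does not show: performance on real
interactomes (10–100× larger, with hubs spanning communities), on noisy
fold-change distributions with correlated errors, on overlapping real
pathway collections, or under annotation errors in molecular roles. The
generator also does not emulate probe-level microarray noise, co-expression
clustering, or functional-annotation term structure — it starts where
those upstream steps end, at a DEG-module table.

## Known limitations

* Identifier namespaces are the user's responsibility; no symbol/ID
  translation is performed (a warning fires when fewer than half of a
  module's genes map into the network).
* The interactome is static and undirected; feedback, inhibition and
  direction of signaling are not represented.
* NAS favors up-regulated pathways by construction of the fold-change
  normalization; studies centered on repression should interpret low NAS
  accordingly.
* Enrichment p-values are uncorrected by design and must not be read as
  calibrated significance levels.
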
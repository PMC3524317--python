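# Methods

## Model and procedure

`cliquesig` treats a gene signature as a set of cliques: gene groups that are
simultaneously (a) differentially expressed between disease and control,
(b) fully interacting in a curated protein–protein interaction (PPI) map, and
(c) fully pairwise co-expressed. Each population (cohort) yields its own
network and clique set; signatures shared by all populations and signatures
unique to one are read off by exact gene-set comparison, and the
neighborhood structure of the cliques is summarized by greedy clique chains
(Clique Connectivity Profiles, CCPs).

### Differential expression

Per gene, a two-sample t-test between disease and control samples
(pooled-variance Student by default; Welch via `test="welch"`). Genes pass
with p < 0.05 **and** Benjamini–Hochberg q < 0.1, both strict. Genes constant
in both groups with equal means are not testable and are excluded outright
rather than assigned p = 1; a constant gene would also contribute nothing to
the correlation filter downstream. Groups of fewer than 2 samples are
refused — a t-test is undefined there.

### Network construction

Nodes are the DE genes that appear in the PPI map; isolated nodes are kept
(they still count in cross-population node censuses) and flagged. A PPI edge
survives only if the Pearson correlation of the two genes' expression
vectors, computed over **all** samples (disease and control pooled),
satisfies |r| > 0.6 strictly. Pooling is a deliberate choice: the filter is
applied once per population network before any group-specific analysis, and
pooling lets the disease shift itself contribute co-expression signal, which
is what makes disease modules cohere. Network summary statistics (diameter,
average path length over unordered reachable pairs) are computed on the
largest connected component, since these networks are almost always
disconnected and the statistics are otherwise undefined.

### Node strength (topology)

Four per-node features: degree; eccentricity score `1 / max_w d(v, w)`
(reciprocal of the farthest reachable node); closeness score
`1 / Σ_w d(v, w)` (sum over the node's component); and betweenness
`Σ_{s≠v≠t} σ_st(v)/σ_st` over unordered pairs, endpoints excluded,
unnormalized (computed with Brandes' algorithm via networkx). Distances are
unweighted hop counts. Unreachable pairs contribute nothing; isolated nodes
score 0 on the three distance features. Each feature is min–max normalized
across the network's nodes and the four are averaged into
`NodeStrength ∈ [0, 1]`. When a feature is constant across the network
(e.g. every feature on a complete graph) all nodes attain its maximum and
receive 1.0 for that feature. Min–max is a declared convention — any
monotone normalization onto [0, 1] would serve; min–max keeps the extremes
interpretable (the hub of a star scores exactly 1).

### Edge strength (biology)

Three per-edge features:

- **|PCC|** — the filter already guarantees |r| > 0.6; the sign is retained
  separately so up/down co-regulation stays reportable.
- **GO similarity** — GO distance is `|A△B| / (|A∪B| + |A∩B|)`: 0 for
  identical non-empty annotation sets, 1 for disjoint sets; a distance < 1
  (≥ 1 shared term) marks the pair as functionally interacting. The
  combined score uses the similarity 1 − distance so that larger = stronger
  for all three features; `go_as_similarity=False` flips this back to the
  raw distance for sensitivity analysis.
- **Pathway similarity** — `(|P∩|/|P_N| + |P∩|/|P_M|) / |P_N ∪ P_M|`, 0 when
  either gene has no pathway annotation. As written this raw score exceeds 1
  for identical singleton sets (value 2); it is applied literally and the
  min–max normalization absorbs the scale.

Genes with no GO (or pathway) annotation leave the feature undefined on
their edges; those edges get the network median of the observed values for
that feature before normalization and carry an `*_unannotated` flag. This
keeps annotation coverage from silently deciding network topology. Features
are min–max normalized across edges (same constant-feature convention as
nodes) and averaged into `EdgeStrength ∈ [0, 1]`.

### Cliques

All k-cliques for k in [3, 7] are enumerated — not only maximal cliques,
because the censuses count cliques per size independently and the CCP walk
operates on fixed-size cliques. Enumeration seeds with triangles and extends
each clique by common neighbors ordered after its last member, which yields
each clique exactly once; correctness is checked against exhaustive subset
enumeration in the tests. A configurable cap (default 10^6 cliques per size)
aborts cleanly on pathologically dense graphs. `CliqueStrength` is the sum
of member NodeStrengths plus internal EdgeStrengths, so a k-clique is
bounded by k + k(k−1)/2 (28 for k = 7).

### Clique Connectivity Profiles

The seed is the clique of the analysis size whose gene set is a clique in
*every* population, maximizing the strength summed over populations. From
the seed, the walk repeatedly inspects unvisited cliques sharing ≥ 1 gene
with the **current chain tail** (not with earlier chain members — the
procedure is stepwise) and appends:

- *MaxCliques*: largest overlap `nn`, then highest strength;
- *MinCliques*: smallest `nn` subject to `nn ≤ 4`, then highest strength.

Residual ties fall to lexicographic gene-set order, so the walk is fully
deterministic; the alternative of emitting all co-optimal successors as
branches is intentionally not followed. The per-link connectivity score is
the mean of the two member strengths. Divergence between populations'
profiles from a shared seed is the first chain position whose gene sets
differ (position 1 = immediately after the seed); chains that agree on the
shorter prefix but differ in length diverge where the shorter ends.

### Enrichment

Upper-tail hypergeometric p-value
`p = Σ_{i=x}^{min(gg,g)} C(g,i) C(G−g, gg−i) / C(G, gg)` for a query of
`gg` genes with `x` annotated, against a background of the `G` population
network genes (`g` annotated) — the network, not the genome, is the correct
reference population for cliques drawn from the network. Unannotated genes
stay in `G` but hit no term. The significance rule is raw p < 0.05; BH q is
reported alongside but does not drive the flag, matching the pipeline's
downstream filtering convention.

## Synthetic data

`generate_suite` emulates a multi-population two-group microarray-style
study. Per gene and sample:

```
value = baseline_g + effect_sd·1[disease & planted DE in this population]
        + clique_factor_sd·f(clique, sample) + N(0, noise_sd)
```

with `baseline_g ~ N(8, 1)` (log2-like scale). Planted cliques occupy
disjoint gene blocks; shared cliques carry their signal in every population,
unique cliques in exactly one. The defaults — effect 5, noise 0.5, unit
within-clique factor, 10+10 samples — put planted genes at ≈ 4.5
within-group SDs of separation and planted pairs at pooled r ≈ 0.97
(the disease shift contributes most of the pooled covariance), so planted
structure clears the p/q and |r| > 0.6 filters with near-certainty and
recovery failures measure pipeline defects, not generator noise. The
residual SD of 0.5 is typical of normalized expression data for expressed
genes.

Background PPI edges (3 per gene on average) always have at least one
non-planted endpoint: since *all* planted genes are disease-shifted, any
two of them are correlated under pooling, and an edge between two different
planted blocks would create cliques the ground truth does not record.
Background genes carry no group effect and are pruned at the DE stage
(occasional false-positive DE genes survive but their pairwise correlations
are near zero, so they contribute no edges). Each planted clique gets a
dedicated GO term and pathway covering exactly its genes, on top of uniform
background annotation.

What the generator does **not** emulate: probe-level effects, batch
effects, heavy-tailed noise, correlated background modules, annotation bias
toward well-studied genes. Passing recovery tests therefore demonstrates
algorithmic correctness of the pipeline on its own model assumptions, not
robustness to real microarray artifacts.

`generate_ccp_fixture` plants per-population clique chains directly at the
clique level (gene sets plus strengths — exactly the inputs of the profile
walk), with consecutive overlap `overlap` and strengths decreasing along the
chain. With `overlap ≤ clique_size/2` non-adjacent cliques are disjoint, so
both linking modes provably reproduce the planted chain. `diverge_at` is the
first position where populations differ; the seed is always shared, so
`diverge_at = 0` is recorded as divergence index 1 ("diverges immediately
after the seed").

## Numerical choices and degenerate inputs

- Strict inequalities throughout (p < 0.05, q < 0.1, |r| > 0.6, p < α).
- Correlation of a constant vector is undefined: the candidate edge is
  dropped, mirroring the exclusion of non-testable genes.
- Zero-variance genes with separated means get t = ±∞, p = 0 (directional
  but degenerate) rather than an error.
- Edgeless networks report diameter and path length 0 with an explicit flag.
- All outputs are serialized in lexicographic order; reruns with identical
  inputs are byte-identical (checked at the file-tree level).

## Problem sizes used in the checks

The recovery analyses run the default study design — 4 populations, 500
genes, 10+10 samples, 5 shared + 2 unique planted 7-cliques per population —
over 20 seeds in the test suite and 5 seeds per invocation of
`scripts/acceptance.py`; oracle comparisons use 1000 random graphs (≤ 50
nodes) for centralities, 200 (≤ 20 nodes) for clique enumeration, and
exhaustive draw enumeration for every hypergeometric configuration with
G ≤ 12. These sizes give the brute-force oracles full coverage of the
regimes the pipeline operates in while keeping a complete run in the order
of a minute.

## Known limitations

- Clique enumeration is exponential in dense graphs; the per-size cap turns
  that into a clean failure, not a workaround.
- The CCP walk is greedy by construction; it does not search for globally
  optimal clique paths, and a single tie broken lexicographically can
  redirect an entire chain suffix.
- GO similarity uses flat annotation sets; no ontology-graph or
  information-content semantics.
- Cross-population clique identity is exact gene-set equality; near-miss
  cliques (6 of 7 genes shared) are reported as different cliques.
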
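# Methods

This note documents the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know about.

## Differential abundance from spectral counts

Spectral counts are normalized by total signal: each sample's counts are
multiplied by (mean sample total / sample total), so all columns end with the
same total. The constant is the mean total rather than, say, the maximum; any
constant gives proportional results, and the mean keeps values on the original
count scale.

The two-class discriminant criterion is implemented as the per-protein one-way
F statistic for two groups, F = (n_a n_b/(n_a+n_b)) (x̄_a−x̄_b)²/s²_p with
df (1, n_a+n_b−2), which is algebraically the square of the pooled-variance t.
With two classes and one variable per test, the discriminant F-ratio and this
statistic coincide; reporting one F and one p per protein admits no other
reduction. Comparisons are pairwise between conditions; batch labels are
carried in the design but not modeled in the test (the nine replicates per
condition are pooled). Proteins with zero counts in every sample of both
compared groups are dropped before testing.

Degenerate inputs: zero pooled variance with equal means returns (F = 0,
p = 1); zero pooled variance with unequal means (perfect separation) returns
the sentinel (F = +inf, p = 0) rather than an error, because the
term-profile comparison legitimately produces all-or-nothing columns and must
retain them. This is the one place the p-value leaves the open interval (0, 1].

Fold change is ln(avSpC_a/avSpC_b), clipped to [−5, +5]; proteins exclusive
to one condition are assigned exactly ±5, making the exclusives the global
extreme of the scale. Antisymmetry under swapping the compared conditions
holds exactly, including for exclusives. Per-protein condition profiles for
display are rescaled so the largest value maps to 100 (an all-zero profile
stays zero).

DAP selection uses F ≥ 5 and p ≤ 0.01 by default; the network-module input
uses the stricter p ≤ 0.001 tier. Both are parameters. Profile clustering is
Ward linkage on Euclidean distances (scipy linkage); dendrograms export to
Newick with branch lengths from merge heights.

## Networks

PPI edge tables are cleaned first (self-edges dropped, unordered duplicates
collapsed keeping the maximum combined score with OR-combined evidence
flags), then filtered on combined score (0.15 for module networks, 0.6 for
condition models) and on evidence: an edge survives when it is database
annotated or experimentally determined. Nodes without surviving edges are
dropped. "Connectedness" for topology is obtained by reduction to the largest
connected component, with ties broken toward the component containing the
lexicographically smallest node id.

Co-expression networks are computed per condition over the core set —
proteins detected (count > 0) in every individual sample of the whole study —
using Spearman rank correlation across that condition's replicates. The
p-value uses the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df (|ρ| = 1
reports p = 0); an exact/Monte-Carlo permutation option exists for small n. At
the default n = 9 the |ρ| ≥ 0.95 threshold already implies p < 1e−4, so the
p ≤ 0.01 condition is exercised but non-binding; it becomes binding for
smaller designs. The absolute value of ρ is thresholded; the signed ρ is kept
as the edge weight for inspection. Constant profiles have undefined ρ and
never gain edges.

## Topology and hubs

Betweenness is unnormalized shortest-path betweenness with endpoints excluded
(networkx). Centroid centrality is C(v) = min over w≠v of γ_v(w) − γ_w(v),
where γ_v(w) counts nodes strictly closer to v than to w (all nodes,
including v and w, are counted); it requires a connected graph and the
implementation refuses disconnected input rather than silently restricting.
Bridging centrality is betweenness(v) × β(v) with the bridging coefficient
β(v) = (1/deg v)/Σ_{i∈N(v)} 1/deg i; isolated nodes get β = 0 by convention.
These two definitions are frozen here (they follow the published descriptions
of the Cytoscape-ecosystem centrality tools) and are verified exactly against
brute-force enumerations — explicit shortest-path listing and explicit γ
counting — on every connected graph with ≤ 6 nodes and on 200 random
connected graphs with ≤ 12 nodes.

A node is a hub when its centrality strictly exceeds the mean over all nodes
of the analyzed component. For PPI models the default rule requires all three
of betweenness, centroid and bridging above their means ("all"); "any" and
"k-of-3" are options, since combining the three admits either reading.
Co-expression hubs use degree alone. Strictly-greater-than makes hub sets
empty on vertex-transitive graphs (cycles, complete graphs), which is the
intended degenerate behaviour.

The scale-free diagnostic fits log10 frequency against log10 degree by least
squares over degrees ≥ 1 with nonzero frequency and declares scale-free when
R² ≥ 0.8 and the slope lies in [−3.5, −1.5]; a discrete maximum-likelihood
exponent α = 1 + n/Σ ln(d_i/(d_min−½)) is reported as a cross-check. Graphs
under 50 nodes return "indeterminate"; a single distinct degree returns
"degenerate". The rule separates preferential-attachment graphs from
same-size Erdős–Rényi graphs cleanly at n = 2000.

## Null models

Degree-preserving randomization uses repeated double edge swaps: pick two
edges (u,v), (x,y) on four distinct nodes and rewire to (u,x), (v,y) when the
result stays simple. The attempt budget is swaps_per_edge × m with
swaps_per_edge = 10, a standard mixing heuristic. Degree multisets are
conserved exactly; graphs admitting no valid swap (e.g., complete graphs) are
returned unchanged with a warning flag. The ensemble default is M = 100.
Ensemble sizes and the randomization model are package choices; both models —
degree-preserving and uniform G(n, m) — are exposed, with G(n, m) the default
suggestion for co-expression networks because near-clique correlation blocks
barely mix under degree-preserving swaps.

Empirical p-values use the add-one rule, p = (1 + #{ensemble ≥ observed})/(M+1)
per tail with the two-sided p twice the smaller tail (capped at 1), so p never
reaches 0 and the floor at M = 100 is ~0.0099. A constant ensemble equal to
the observed value reports z = 0 with a degenerate flag; the constancy check
uses a relative tolerance of 1e−12 because bitwise-identical ensemble values
can still produce a subnormal standard deviation through summation rounding.

## Enrichment

Term enrichment for module grouping is the upper-tail hypergeometric
P[X ≥ k] with Benjamini–Hochberg FDR across tested terms (q ≤ 0.01 default).
Per-replicate term profiles use the one-sided Fisher exact test (identical to
the hypergeometric tail on the same margins — asserted against 500 random
tables) with Bonferroni correction (α = 0.05). Term profiles across
conditions are compared with the same two-group F as the protein tests; the
per-replicate score is −log10 of the raw Fisher p by default, with a 0/1
indicator encoding available, since the original profile encoding is not
uniquely determined. The universe is the annotation map's universe,
optionally intersected with the detected proteome (the pipeline uses the
intersection). Annotations are taken as given: no ontology-graph propagation.

## The synthetic-data generator

Counts are negative binomial with variance μ + φμ² (φ = dispersion, default
0.2), the standard over-dispersed model for spectral counts; the real study
reports no count-level variance parameters, so the defaults are documented
assumptions, not estimates. Per-protein baselines are log-normal around a
mean of 20 counts with log-sd 1 (heavy-tailed abundances); per-sample
library-size factors and per-protein-per-batch effects are mean-one
log-normal with sd 0.1 each. The design defaults to the study shape: 4
conditions × 9 replicates allocated round-robin across 3 batches. An optional
batch-specific dropout zeroes detections at a per-batch increasing rate
(default off).

Planted structure: a fraction of proteins (default 5%) get their mean
multiplied by exp(±effect) in the treated condition (default effect ln FC 2);
exclusives (default 2%) are hard-zeroed there and mean-floored elsewhere, with
a structural guarantee of at least one nonzero count per other condition, so
the ±5 rule is exercised deterministically rather than probabilistically.
Co-expression blocks replace their proteins' counts with distinct gains times
a shared latent monotone driver drawn independently per condition, giving
within-block Spearman ρ = 1 at zero noise while keeping cross-block profiles
independent. Bridged networks join two independently grown
preferential-attachment communities only through designated bridge nodes
anchored at each community's highest-degree node — the simplest topology with
an unambiguous bridging-centrality winner. The planted annotation term draws
its configured fraction of members from the planted DAPs and the remainder
from outside them, so at the random-expectation fraction the planted term is
statistically indistinguishable from the rest.

What the generator does not emulate: peptide-to-protein inference and
identification-level FDR, correlated protein abundances outside the planted
blocks, missing-not-at-random dropout tied to abundance, and real
interaction-database structure (scores and evidence flags are drawn
independently of topology). Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under the stated model, not its
performance on any particular real data set.

## Problem sizes and verification

The end-to-end run and the acceptance computations use a 3000-protein study,
a 400-node interaction network with one planted bridge, 50-term annotation
maps, and null ensembles of M = 100; recovery rates (bridge hubs,
co-expression blocks) aggregate 50 seeded replicates, and calibration uses
2000–3000 null proteins, sizes at which the binomial confidence interval
around the nominal 1% type-I rate is a meaningful check. Under these
conditions the DAP caller's observed type-I rate sits inside the 99% CI of
0.01, power at |ln FC| = 2 with n = 9 per group exceeds 0.95, and every
planted structure is recovered at or near 100%; the exact numbers for a given
seed are produced by `scripts/acceptance.py`.

## Known limitations

The F test assumes approximately normal within-group variation; on strongly
over-dispersed counts (φ well above the default) its calibration drifts, and
a count-model test (e.g., negative-binomial regression) would be preferable —
that is outside this package's scope, which reproduces the spectral-count
LDA/F procedure. Centroid centrality is O(n²) memory-light but O(n³) time in
the vectorized loop, practical to a few thousand nodes. The Spearman
permutation option enumerates exhaustively only for n ≤ 7 and falls back to
Monte Carlo above. Venn region computation supports at most 4 sets.
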
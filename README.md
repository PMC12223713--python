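# protnet

Proteome network inference from label-free spectral counts.

`protnet` is for proteomics and systems-biology researchers who quantify
proteins by spectral counting (the number of MS/MS spectra matched to a
protein) across a multi-condition, multi-replicate design and want to go from
the raw count matrix to condition-specific interaction networks, topological
hubs and functional modules. The reference design it emulates is a study of
*Arabidopsis thaliana* chloroplast-biogenesis perturbation: four conditions
(wild type and a retrograde-signalling mutant, each with and without the
chloroplast translation inhibitor lincomycin), nine replicates per condition
drawn from three acquisition batches.

## The method

**Differential abundance.** Counts are normalized by total signal,
nSpC(i,j) = SpC(i,j) · mean(totals)/total(j), so every sample carries the same
signal mass. For each protein and each pairwise condition comparison the
two-class linear-discriminant criterion reduces to the one-way F statistic

F = (n_a·n_b/(n_a+n_b)) · (x̄_a − x̄_b)² / s²_p,   df = (1, n_a + n_b − 2),

which equals the square of the pooled-variance t statistic. Differentially
abundant proteins (DAPs) satisfy F ≥ 5 and p ≤ 0.01 (a high-confidence tier at
p ≤ 0.001 feeds the module networks). Fold change is ln(avSpC_a/avSpC_b)
capped at ±5; proteins detected in only one of the two conditions are set to
exactly ±5. DAP profiles are clustered with Ward linkage on Euclidean
distances.

**Networks.** PPI networks are filtered from a scored, evidence-flagged edge
table (STRING-download layout): combined score ≥ 0.15 for differential-module
networks and ≥ 0.6 for condition-level models, keeping only interactions
annotated in databases and/or experimentally determined. Co-expression
networks join core proteins (detected in every sample of the study) whose
per-condition profiles have Spearman |ρ| ≥ 0.95 with p ≤ 0.01.

**Topology and hubs.** PPI models are scored with unnormalized betweenness,
centroid centrality C(v) = min_w [γ_v(w) − γ_w(v)] (γ_v(w) = number of nodes
strictly closer to v than to w), and bridging centrality
betweenness(v) · (1/deg v)/Σ_{i∈N(v)} (1/deg i); co-expression models with
node degree. A node is a hub when its centralities exceed the network-wide
average (by default in all three metrics for PPI). Observed statistics are
tested against degree-preserving double-edge-swap ensembles (or same-n-same-m
uniform graphs) with add-one-rule empirical p-values, and degree distributions
are checked for scale-free shape by a log–log least-squares fit.

**Enrichment.** DAPs are grouped into functional modules by upper-tail
hypergeometric term enrichment with Benjamini–Hochberg FDR (q ≤ 0.01);
per-replicate term profiles use one-sided Fisher exact tests with Bonferroni
correction (p ≤ 0.05) and are compared across conditions with the same F
criterion.

**Synthetic studies.** `protnet.simulate` generates the whole study shape with
recorded ground truth: negative-binomial counts (variance μ + φμ²) with
heavy-tailed baselines, library-size and batch effects, planted DAPs and
condition-exclusive proteins, planted monotone co-expression blocks, scale-free
networks with planted bridge nodes, and annotation maps with a planted
enriched term — so every downstream stage is testable against known truth.

## Worked example

```python
from protnet import (SimDesign, simulate_counts, normalize_total_signal,
                     differential_abundance, select_daps)

design = SimDesign(n_proteins=500, seed=42)          # 4 conditions x 9 replicates
matrix, truth = simulate_counts(design, effect_ln_fc=2.0,
                                frac_dap=0.05, frac_exclusive=0.02)
norm = normalize_total_signal(matrix)
records = differential_abundance(norm, ("Col-0", "Col-0+Lin"))
daps = select_daps(records, f_min=5, p_max=0.01)

print(f"tested {len(records)} proteins, called {len(daps)} DAPs")
called = set(daps["protein"])
planted = set(truth.dap_ids) | set(truth.exclusive_ids)
print(f"recall of planted effects: {len(called & planted) / len(planted):.2f}")
print(daps.sort_values("p").head(5).to_string(index=False))
```

prints

```
tested 500 proteins, called 39 DAPs
recall of planted effects: 0.94
protein         comparison   avA    avB     F        p  lnFC exclusive
 P00090 Col-0 vs Col-0+Lin 27.12   0.00 117.9 8.62e-09  5.00    a_only
 P00079 Col-0 vs Col-0+Lin 26.90   3.00 103.6 2.15e-08  2.19      none
 P00373 Col-0 vs Col-0+Lin 23.11   0.00  70.6 2.93e-07  5.00    a_only
 P00325 Col-0 vs Col-0+Lin 74.99  10.61  66.4 4.35e-07  1.96      none
 P00234 Col-0 vs Col-0+Lin 39.92 226.86  62.7 6.32e-07 -1.74      none
```

The two `a_only` rows are proteins simulated as exclusive to the first
condition: their fold change is pinned to exactly +5. The remaining hits are
planted two-unit (on the natural-log scale) abundance shifts; 39 calls out of
500 proteins at ~94% recall of the 35 planted effects reflects the caller's
power at n = 9 per group.

The same analysis runs end to end from a YAML config (`protnet pipeline
--config run.yaml`) or stage by stage via the other subcommands
(`simulate`, `normalize`, `dap`, `ppi`, `coexpr`, `topology`, `nulls`,
`enrich`, `overlap`).

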
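# diffcornet

Differential correlation network analysis for two-group targeted
metabolomics.

Metabolite concentrations are correlated with one another because they sit
in shared biochemical pathways, and those correlations can differ between
conditions — here, between female and male subjects — even when no single
metabolite differs in mean abundance. `diffcornet` quantifies such
rewiring: it compares the metabolite–metabolite Pearson correlation
structure of two groups, tests each pair by permutation, assembles the
significant pairs into a signed network, and ranks metabolites by network
centrality to flag the hubs and bottlenecks of the sex-differential
metabolome. It is aimed at metabolomics and systems-biology analysts
working with targeted panels (e.g. a Biocrates-p180-style panel of ~168
metabolites) and two-group cohort designs.

## Method

For metabolites *i*, *j* with within-group Pearson correlations
*r*<sub>f</sub> and *r*<sub>m</sub> (n<sub>f</sub> female, n<sub>m</sub>
male samples), the differential correlation statistic is the normalized
difference of Fisher z-transformations

```
z(r)   = ½ · ln((1 + r) / (1 − r))                         (Fisher z)
r_diff = √((n_f − 3)/2) · z(r_f)  −  √((n_m − 3)/2) · z(r_m)
```

Because z(r) of a sample correlation is approximately normal with variance
1/(n − 3), each term has variance ≈ ½ and r_diff is approximately standard
normal when both groups are uncorrelated; positive values mean the pair is
more strongly correlated in females. Significance is assessed by a
label-shuffling permutation test (sex labels permuted across all samples,
group sizes preserved; two-sided add-one p-value), which is exact under
label exchangeability regardless of the asymptotics. Pairs with p < α
(default 0.05) form an undirected network whose nodes are ranked by degree,
normalized betweenness and Wasserman–Faust closeness; the union of the
top-k nodes per metric (default k = 14) are the key metabolites, split into
hubs (high degree) and bottlenecks (high betweenness/closeness).

Before correlation the pipeline applies the standard pre-processing
sequence: within-sex mean imputation of missing values, linear
residualization on age and BMI, and z-normalization.

A synthetic-data generator (`diffcornet.simulate`) produces cohorts with
planted group-specific correlation structure, age/BMI confounding and
missingness, so every stage is testable against known ground truth.

## Worked example

```python
from diffcornet import (PanelSpec, default_scenario, generate, preprocess,
                        permutation_test, select_significant, build_network,
                        network_summary, centrality_table, rank_key_nodes)

spec = PanelSpec(n_metabolites=40, n_female=140, n_male=96)
ds = generate(spec, default_scenario(40), seed=3)
pre = preprocess(ds.concentrations, ds.phenotypes)
edges = permutation_test(pre, ds.phenotypes, B=500, seed=4)
sig = select_significant(edges, alpha=0.05)
G = build_network(sig)
print(network_summary(G))
print(rank_key_nodes(centrality_table(G), top_k=5).head(3))
```

prints

```
{'n_nodes': 39, 'n_edges': 81, 'n_positive': 58, 'n_negative': 23,
 'mean_degree': 4.153846153846154, 'empty': False}
  metabolite  degree  betweenness  closeness  is_hub  is_bottleneck  is_key
0         C4      11     0.238...   0.494...    True           True    True
1         C0      11     0.063...   0.475...    True           True    True
2         C3       9     0.230...   0.475...    True           True    True
```

Of 780 metabolite pairs, 81 show a sex difference in correlation that
survives the permutation test — 58 stronger in females (positive), 23
stronger in males (negative). The planted differential-module center `C0`
is recovered at the top of the degree ranking and is flagged both hub and
bottleneck. The `examples/` directory holds one short script per
capability (simulation, the pair statistic, the full pipeline, centrality
ranking); each prints its numbers with a line of interpretation.

The same analysis is available from the shell:

```
diffcornet simulate --n-metabolites 40 --outdir sim
diffcornet run-all --seed 1 --permutations 1000 --outdir run
```

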
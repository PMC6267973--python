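"""Key-metabolite identification: degree, betweenness, closeness.

Builds the differential network from a simulated run and prints the
key-node table (hubs = top-k degree; bottlenecks = top-k betweenness or
closeness), the shape of a core-metabolite report.
"""

from diffcornet import (
    PanelSpec,
    build_network,
    centrality_table,
    default_scenario,
    generate,
    network_summary,
    permutation_test,
    preprocess,
    rank_key_nodes,
    select_significant,
)

spec = PanelSpec(n_metabolites=40, n_female=140, n_male=96)
ds = generate(spec, default_scenario(40), seed=3)
pre = preprocess(ds.concentrations, ds.phenotypes)
edges = permutation_test(pre, ds.phenotypes, B=500, seed=4)
sig = select_significant(edges, alpha=0.05)

G = build_network(sig)
s = network_summary(G)
print(f"network: {s['n_nodes']} nodes, {s['n_edges']} edges "
      f"({s['n_positive']} positive, {s['n_negative']} negative), "
      f"mean degree {s['mean_degree']:.2f}")

ranked = rank_key_nodes(centrality_table(G), top_k=5)
key = ranked[ranked["is_key"]]
print("\nkey metabolites (top-5 union by degree/betweenness/closeness):")
print(key.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nThe planted module center 'C0' sits at or near the top of the degree "
      "column: it is the metabolite whose correlations differ most broadly "
      "between the sexes.")
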
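"""Simulate a two-group metabolomics dataset with planted structure.

Builds a 40-metabolite panel on 140 female / 96 male subjects with a
differential hub module (metabolite "C0" correlated with ten partners in
females only), prints the dataset shape and a planted-vs-empirical
correlation comparison for one pair.
"""

import numpy as np

from diffcornet import PanelSpec, default_scenario, generate

spec = PanelSpec(n_metabolites=40, n_female=140, n_male=96)
scenario = default_scenario(40)
ds = generate(spec, scenario, seed=42)

print(f"concentrations: {ds.concentrations.n_samples} samples x "
      f"{ds.concentrations.n_metabolites} metabolites")
print(f"missing cells: {int(ds.concentrations.missing_mask.to_numpy().sum())} "
      f"(rate {scenario.missing_rate})")
print(f"planted differential pairs: {len(ds.truth)}")

pair = ds.truth.iloc[0]
female = ds.phenotypes.female_mask(ds.concentrations.sample_ids)
X = ds.concentrations.values.to_numpy()
i, j = int(pair["i"]), int(pair["j"])
ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
rf = np.corrcoef(X[female & ok][:, [i, j]], rowvar=False)[0, 1]
rm = np.corrcoef(X[~female & ok][:, [i, j]], rowvar=False)[0, 1]
print(f"\npair {pair['metabolite_i']} - {pair['metabolite_j']}:")
print(f"  planted   r_female = {pair['r_female_true']:.2f}, r_male = {pair['r_male_true']:.2f}")
print(f"  empirical r_female = {rf:.2f}, r_male = {rm:.2f}")
print("The empirical within-sex correlations track the planted values up to "
      "sampling noise — this is the signal the pipeline is asked to recover.")
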
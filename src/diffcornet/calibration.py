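"""Simulation studies of the method's operating characteristics.

Each function runs the package end to end on synthetic data of known
structure and measures one property: the null distribution of the
differential correlation statistic, the type-I error of the permutation
test, its power against a planted pair, and recovery of a planted hub
metabolite by network degree.  These are the quantitative checks behind
the package's claims; the test suite and the reproduction script both
call them.
"""

from __future__ import annotations

import numpy as np

from .diffcorr import all_pairs_diffcorr, permutation_test, select_significant
from .network import build_network
from .simulate import (
    CorrelationScenario,
    PanelSpec,
    generate,
    one_factor_block_plants,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def null_rdiff_sample(
    n_pairs: int = 10_000,
    n_female: int = 140,
    n_male: int = 96,
    metabolites_per_dataset: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """r_diff values for uncorrelated pairs with no group difference.

    Draws independent null datasets (identity correlation in both groups)
    until at least ``n_pairs`` pairs are collected.  Under the half-scaled
    statistic the values should be approximately standard normal.
    """
    spec = PanelSpec(
        n_metabolites=metabolites_per_dataset, n_female=n_female, n_male=n_male
    )
    scenario = CorrelationScenario()
    per = metabolites_per_dataset * (metabolites_per_dataset - 1) // 2
    n_datasets = -(-n_pairs // per)
    out = []
    for s in _child_seeds(seed, n_datasets):
        ds = generate(spec, scenario, seed=s)
        edges = all_pairs_diffcorr(ds.concentrations, ds.phenotypes)
        out.append(edges["r_diff"].to_numpy())
    return np.concatenate(out)[:n_pairs]


def permutation_type1_rate(
    n_datasets: int = 200,
    n_metabolites: int = 10,
    n_female: int = 140,
    n_male: int = 96,
    B: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null pairs rejected at ``alpha`` (should be ~alpha)."""
    spec = PanelSpec(n_metabolites=n_metabolites, n_female=n_female, n_male=n_male)
    scenario = CorrelationScenario()
    rejected = total = 0
    seeds = _child_seeds(seed, 2 * n_datasets)
    for k in range(n_datasets):
        ds = generate(spec, scenario, seed=seeds[2 * k])
        edges = permutation_test(
            ds.concentrations, ds.phenotypes, B=B, seed=seeds[2 * k + 1]
        )
        rejected += int((edges["p_perm"] < alpha).sum())
        total += len(edges)
    return rejected / total


def planted_pair_power(
    n_reps: int = 100,
    r_female: float = 0.8,
    r_male: float = 0.0,
    n_female: int = 140,
    n_male: int = 96,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates where one planted differential pair is detected."""
    spec = PanelSpec(n_metabolites=2, n_female=n_female, n_male=n_male)
    scenario = CorrelationScenario(planted_edges=[(0, 1, r_female, r_male)])
    seeds = _child_seeds(seed, 2 * n_reps)
    hits = 0
    for k in range(n_reps):
        ds = generate(spec, scenario, seed=seeds[2 * k])
        edges = permutation_test(
            ds.concentrations, ds.phenotypes, B=B, seed=seeds[2 * k + 1]
        )
        hits += int(edges.loc[0, "p_perm"] < alpha)
    return hits / n_reps


def hub_recovery_rate(
    n_reps: int = 50,
    n_metabolites: int = 30,
    n_partners: int = 10,
    r_female: float = 0.5,
    n_female: int = 140,
    n_male: int = 96,
    B: int = 200,
    alpha: float = 0.05,
    top: int = 5,
    seed: int = 0,
) -> float:
    """How often a planted differential-module center ranks top-``top`` by degree.

    Each replicate plants a one-factor module (center metabolite 0 with
    ``n_partners`` partners, correlated only in females), runs the full
    significance pipeline and checks the center's degree rank in the
    resulting network (fewer than ``top`` nodes with strictly higher degree).
    """
    spec = PanelSpec(n_metabolites=n_metabolites, n_female=n_female, n_male=n_male)
    plants = one_factor_block_plants(0, list(range(1, n_partners + 1)), r_female)
    scenario = CorrelationScenario(planted_edges=plants)
    center = spec.metabolite_names()[0]
    seeds = _child_seeds(seed, 2 * n_reps)
    hits = 0
    for k in range(n_reps):
        ds = generate(spec, scenario, seed=seeds[2 * k])
        edges = permutation_test(
            ds.concentrations, ds.phenotypes, B=B, seed=seeds[2 * k + 1]
        )
        sig = select_significant(edges, alpha=alpha)
        if len(sig) == 0:
            continue
        G = build_network(sig)
        if center not in G:
            continue
        degrees = dict(G.degree())
        higher = sum(1 for d in degrees.values() if d > degrees[center])
        hits += int(higher < top)
    return hits / n_reps


def antisymmetry_deviation(
    n_metabolites: int = 20,
    n_female: int = 140,
    n_male: int = 96,
    seed: int = 0,
) -> float:
    """Max |r_diff(labels) + r_diff(swapped labels)| on one simulated dataset.

    Exchanging every sample's sex label must negate the statistic exactly.
    """
    spec = PanelSpec(n_metabolites=n_metabolites, n_female=n_female, n_male=n_male)
    ds = generate(spec, CorrelationScenario(), seed=seed)
    swapped = ds.phenotypes.copy()
    swapped.data["sex"] = swapped.data["sex"].map({"female": "male", "male": "female"})
    a = all_pairs_diffcorr(ds.concentrations, ds.phenotypes)["r_diff"].to_numpy()
    b = all_pairs_diffcorr(ds.concentrations, swapped)["r_diff"].to_numpy()
    return float(np.max(np.abs(a + b)))
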
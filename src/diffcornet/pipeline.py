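"""End-to-end run: simulate (or load) -> preprocess -> differential
correlation with permutation significance -> network and key metabolites.

All outputs of :func:`run_all` land in one run directory and are plain
text (CSV, GraphML, JSON); identical configuration and seed give a
byte-identical directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, io, network
from .datatypes import ConcentrationTable, PhenotypeTable
from .diffcorr import permutation_test, select_significant
from .preprocess import preprocess
from .simulate import CorrelationScenario, PanelSpec, default_scenario, generate

log = logging.getLogger("diffcornet")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def truth_detection(truth: pd.DataFrame, significant: pd.DataFrame) -> pd.DataFrame:
    """Mark which planted differential pairs were recovered as significant."""
    detected = {
        _pair_key(r.metabolite_i, r.metabolite_j): r.p_perm
        for r in significant.itertuples(index=False)
    }
    out = truth.copy()
    keys = [
        _pair_key(a, b) for a, b in zip(out["metabolite_i"], out["metabolite_j"])
    ]
    out["detected"] = [k in detected for k in keys]
    out["p_perm"] = [detected.get(k) for k in keys]
    return out


def run_all(
    config: io.PipelineConfig,
    scenario: CorrelationScenario | None = None,
) -> tuple[Path, dict]:
    """Execute the whole pipeline; returns the run directory and metadata.

    With no input paths in ``config`` the run simulates its own dataset:
    ``scenario`` overrides the reference scenario if given.  Files written:
    (simulated only) ``concentrations.csv``/``phenotypes.csv``/``truth.csv``
    and ``truth_detection.csv``; always ``preprocessed.csv``,
    ``edges_all.csv``, ``edges_significant.csv``, ``node_metrics.csv``,
    ``network.graphml``, ``run_metadata.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_seed, perm_seed = io.derive_seeds(config.seed)

    truth = None
    if config.simulated:
        spec = PanelSpec(
            n_metabolites=config.n_metabolites,
            n_female=config.n_female,
            n_male=config.n_male,
        )
        if scenario is None:
            scenario = default_scenario(config.n_metabolites)
        ds = generate(spec, scenario, seed=sim_seed)
        conc, pheno, truth = ds.concentrations, ds.phenotypes, ds.truth
        io.write_concentrations(conc, outdir / "concentrations.csv")
        io.write_phenotypes(pheno, outdir / "phenotypes.csv")
        io.write_truth(truth, outdir / "truth.csv")
        log.info("simulated %d samples x %d metabolites", conc.n_samples, conc.n_metabolites)
    else:
        conc = io.read_concentrations(config.concentrations)
        pheno = io.read_phenotypes(config.phenotypes)
        log.info("loaded %d samples x %d metabolites", conc.n_samples, conc.n_metabolites)

    n_missing = int(conc.missing_mask.to_numpy().sum())
    pre = preprocess(
        conc, pheno,
        adjust_scope=config.adjust_scope,
        sd_convention=config.sd_convention,
    )
    io.write_concentrations(pre, outdir / "preprocessed.csv")
    log.info("preprocessed: %d missing cells imputed", n_missing)

    edges = permutation_test(
        pre, pheno, B=config.permutations, seed=perm_seed, scale=config.scale
    )
    io.write_edges(edges, outdir / "edges_all.csv")
    sig = select_significant(
        edges, alpha=config.alpha, multiple_testing=config.multiple_testing
    )
    io.write_edges(sig, outdir / "edges_significant.csv")
    log.info(
        "%d/%d pairs significant at alpha=%g (%d positive, %d negative)",
        len(sig), len(edges), config.alpha,
        sig.attrs["n_positive"], sig.attrs["n_negative"],
    )

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty network is a valid outcome
        G = network.build_network(sig)
    summary = network.network_summary(G)
    metrics = network.centrality_table(G, config.closeness_convention)
    metrics = network.rank_key_nodes(metrics, top_k=config.top_k)
    io.write_node_metrics(metrics, outdir / "node_metrics.csv")
    network.write_graphml(G, outdir / "network.graphml")

    metadata = {
        "software": {"name": "diffcornet", "version": __version__},
        "config": config.to_dict(),
        "derived_seeds": {"simulation": sim_seed, "permutation": perm_seed},
        "counts": {
            "n_samples": conc.n_samples,
            "n_metabolites": conc.n_metabolites,
            "n_female": pheno.n_female,
            "n_male": pheno.n_male,
            "n_missing_cells_imputed": n_missing,
            "n_pairs_tested": int(len(edges)),
            "n_significant": int(len(sig)),
            "n_significant_positive": sig.attrs["n_positive"],
            "n_significant_negative": sig.attrs["n_negative"],
            "n_network_nodes": summary["n_nodes"],
            "mean_degree": summary["mean_degree"],
        },
    }
    if truth is not None and len(truth):
        report = truth_detection(truth, sig)
        report.to_csv(outdir / "truth_detection.csv", index=False, na_rep="NA")
        metadata["truth"] = {
            "n_planted_differential": int((truth["delta_true"].abs() > 1e-12).sum()),
            "n_planted_detected": int(
                report.loc[report["delta_true"].abs() > 1e-12, "detected"].sum()
            ),
        }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir, metadata
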
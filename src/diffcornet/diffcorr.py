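"""Differential correlation: per-sex Pearson r, the normalized Fisher-z
difference statistic, and permutation significance by sex-label shuffling.

For metabolites i, j with within-sex Pearson correlations r_f and r_m the
differential correlation is

    r_diff = c(n_f) * atanh(r_f) - c(n_m) * atanh(r_m)

where atanh is the Fisher z-transformation and, under the default
``scale="half"`` convention, c(n) = sqrt((n - 3) / 2).  Since atanh(r) of a
sample correlation is approximately normal with variance 1/(n - 3), the two
terms then each have variance ~1/2 and r_diff is approximately standard
normal when both groups share a zero correlation.  ``scale="full"`` uses
c(n) = sqrt(n - 3) instead.

Significance is assessed by shuffling the sex labels across all samples
(group sizes preserved) and recomputing r_diff; the two-sided p-value uses
the add-one estimator p = (1 + #{|r_diff_perm| >= |r_diff_obs|}) / (B + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConcentrationTable, PhenotypeTable, align

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "diff_corr",
    "group_correlations",
    "all_pairs_diffcorr",
    "permutation_test",
    "select_significant",
]

#: clamp applied to |r| before the z-transform so r = +-1 stays finite
CLAMP_EPS = 1e-7

EDGE_COLUMNS = [
    "metabolite_i", "metabolite_j", "r_female", "r_male",
    "z_female", "z_male", "r_diff", "p_normal", "p_perm", "sign",
]


def fisher_z(r):
    """Fisher z-transformation z = 0.5 * ln((1 + r) / (1 - r)).

    Accepts scalars or arrays with |r| <= 1; inputs within CLAMP_EPS of
    +-1 (including exactly +-1) are clamped so the result stays finite.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlation coefficient must satisfy |r| <= 1")
    z = np.arctanh(np.clip(arr, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS))
    return z if arr.ndim else float(z)


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if np.ndim(z) else float(out)


def _scale_factor(n: int, scale: str) -> float:
    if n <= 3:
        raise ValueError(f"group size {n} too small: the scale factor needs n > 3")
    if scale == "half":
        return float(np.sqrt((n - 3) / 2.0))
    if scale == "full":
        return float(np.sqrt(n - 3.0))
    raise ValueError(f"unknown scale convention {scale!r}; use 'half' or 'full'")


def diff_corr(r_f, r_m, n_f: int, n_m: int, scale: str = "half"):
    """Normalized difference of Fisher-z transformed group correlations."""
    cf, cm = _scale_factor(n_f, scale), _scale_factor(n_m, scale)
    return cf * fisher_z(r_f) - cm * fisher_z(r_m)


def _group_matrices(
    conc: ConcentrationTable, pheno: PhenotypeTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    conc, pheno = align(conc, pheno, min_group=4)
    X = conc.values.to_numpy()
    if np.isnan(X).any():
        raise ValueError("differential correlation requires complete data; preprocess first")
    female = pheno.female_mask(conc.sample_ids)
    for group, mask in (("female", female), ("male", ~female)):
        sd = X[mask].std(axis=0)
        if np.any(sd == 0):
            name = conc.metabolite_names[int(np.argmax(sd == 0))]
            raise ValueError(
                f"metabolite {name!r} has zero variance within the {group} group"
            )
    return X, female, X[female]


def group_correlations(
    conc: ConcentrationTable, pheno: PhenotypeTable
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Within-sex Pearson correlation matrices (r_female, r_male, n_f, n_m)."""
    X, female, _ = _group_matrices(conc, pheno)
    Rf = np.corrcoef(X[female], rowvar=False)
    Rm = np.corrcoef(X[~female], rowvar=False)
    return Rf, Rm, int(female.sum()), int((~female).sum())


def _rdiff_matrix(X: np.ndarray, female: np.ndarray, cf: float, cm: float) -> np.ndarray:
    Rf = np.corrcoef(X[female], rowvar=False)
    Rm = np.corrcoef(X[~female], rowvar=False)
    np.clip(Rf, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS, out=Rf)
    np.clip(Rm, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS, out=Rm)
    return cf * np.arctanh(Rf) - cm * np.arctanh(Rm)


def all_pairs_diffcorr(
    conc: ConcentrationTable, pheno: PhenotypeTable, scale: str = "half"
) -> pd.DataFrame:
    """Edge table of r_diff over all m*(m-1)/2 metabolite pairs.

    Columns follow ``EDGE_COLUMNS``; ``p_perm`` is NaN until
    :func:`permutation_test` fills it.  ``p_normal`` is the two-sided
    standard-normal tail probability of r_diff, a diagnostic only — the
    permutation p-value is the inference the pipeline uses.
    """
    Rf, Rm, n_f, n_m = group_correlations(conc, pheno)
    cf, cm = _scale_factor(n_f, scale), _scale_factor(n_m, scale)
    names = conc.metabolite_names
    iu, ju = np.triu_indices(len(names), k=1)
    rf, rm = Rf[iu, ju], Rm[iu, ju]
    zf, zm = fisher_z(rf), fisher_z(rm)
    rdiff = cf * zf - cm * zm
    p_normal = 2.0 * stats.norm.sf(np.abs(rdiff)) if scale == "half" else np.full_like(rdiff, np.nan)
    edges = pd.DataFrame(
        {
            "metabolite_i": [names[i] for i in iu],
            "metabolite_j": [names[j] for j in ju],
            "r_female": rf,
            "r_male": rm,
            "z_female": zf,
            "z_male": zm,
            "r_diff": rdiff,
            "p_normal": p_normal,
            "p_perm": np.nan,
            "sign": np.where(rdiff >= 0, "positive", "negative"),
        }
    )
    edges.attrs.update({"n_female": n_f, "n_male": n_m, "scale": scale})
    return edges


def permutation_test(
    conc: ConcentrationTable,
    pheno: PhenotypeTable,
    B: int = 1000,
    seed: int | None = None,
    scale: str = "half",
    edges: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation p-values for every pair by shuffling sex labels.

    Each of the ``B`` permutations redraws which samples count as female
    (group sizes fixed at the observed n_f, n_m), recomputes the full
    r_diff matrix and compares magnitudes against the observed statistic.
    One seeded generator drives the whole permutation stream, so the
    result is reproducible from ``seed`` alone.
    """
    if B < 1:
        raise ValueError("the number of permutations B must be >= 1")
    X, female, _ = _group_matrices(conc, pheno)
    n_f, n_m = int(female.sum()), int((~female).sum())
    cf, cm = _scale_factor(n_f, scale), _scale_factor(n_m, scale)
    if edges is None:
        edges = all_pairs_diffcorr(conc, pheno, scale=scale)
    obs = np.abs(_rdiff_matrix(X, female, cf, cm))
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    exceed = np.zeros_like(obs)
    for _ in range(B):
        perm_female = female[rng.permutation(n)]
        exceed += np.abs(_rdiff_matrix(X, perm_female, cf, cm)) >= obs
    iu, ju = np.triu_indices(X.shape[1], k=1)
    out = edges.copy()
    out["p_perm"] = (1.0 + exceed[iu, ju]) / (B + 1.0)
    out.attrs.update(edges.attrs)
    out.attrs.update({"B": B, "seed": seed})
    return out


def select_significant(
    edges: pd.DataFrame, alpha: float = 0.05, multiple_testing: str = "none"
) -> pd.DataFrame:
    """Edges with permutation p-value strictly below ``alpha``.

    ``multiple_testing="bh"`` instead thresholds Benjamini-Hochberg
    adjusted p-values (added as a ``p_adj`` column).  The attrs of the
    returned frame carry the positive/negative edge counts.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if edges["p_perm"].isna().any():
        raise ValueError("p_perm unset; run permutation_test first")
    if multiple_testing == "bh":
        from statsmodels.stats.multitest import multipletests

        edges = edges.copy()
        edges["p_adj"] = multipletests(edges["p_perm"], method="fdr_bh")[1]
        kept = edges[edges["p_adj"] < alpha].copy()
    elif multiple_testing == "none":
        kept = edges[edges["p_perm"] < alpha].copy()
    else:
        raise ValueError(f"unknown multiple-testing mode {multiple_testing!r}")
    kept.reset_index(drop=True, inplace=True)
    kept.attrs.update(edges.attrs)
    kept.attrs["n_positive"] = int((kept["sign"] == "positive").sum())
    kept.attrs["n_negative"] = int((kept["sign"] == "negative").sum())
    return kept


def sort_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Canonical report order: |r_diff| descending, ties by names."""
    out = edges.copy()
    out["_abs"] = out["r_diff"].abs()
    out = out.sort_values(
        ["_abs", "metabolite_i", "metabolite_j"], ascending=[False, True, True]
    ).drop(columns="_abs")
    out.reset_index(drop=True, inplace=True)
    out.attrs.update(edges.attrs)
    return out
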
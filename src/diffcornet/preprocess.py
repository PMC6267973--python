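"""Pre-processing: sex-stratified mean imputation, covariate adjustment,
z-normalization.

The three steps run in that fixed order.  Imputation fills each missing
value with the mean of the observed values of the same metabolite within
the same sex group.  Covariate adjustment replaces each metabolite by the
residuals of an ordinary least-squares fit on intercept + age + BMI,
removing linear confounding by those variables.  Normalization brings every
metabolite to zero mean and unit standard deviation over the pooled sample.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    SEXES,
    ConcentrationTable,
    DataValidationError,
    PhenotypeTable,
    align,
)

__all__ = [
    "impute_by_sex",
    "adjust_covariates",
    "znormalize",
    "preprocess",
    "PreprocessError",
]


class PreprocessError(ValueError):
    pass


def impute_by_sex(conc: ConcentrationTable, pheno: PhenotypeTable) -> ConcentrationTable:
    """Fill missing entries with the within-sex mean of the metabolite.

    Observed entries are untouched.  A metabolite with no observed value in
    one sex cannot be imputed there and raises :class:`PreprocessError`
    naming the metabolite and sex.
    """
    conc, pheno = align(conc, pheno, min_group=1)
    values = conc.values.copy()
    X = values.to_numpy()
    female = pheno.female_mask(conc.sample_ids)
    for sex, mask in zip(SEXES, (female, ~female)):
        sub = X[mask]
        observed = ~np.isnan(sub)
        n_obs = observed.sum(axis=0)
        if np.any(n_obs == 0):
            name = conc.metabolite_names[int(np.argmax(n_obs == 0))]
            raise PreprocessError(
                f"metabolite {name!r} has no observed value in sex group {sex!r}"
            )
        with np.errstate(invalid="ignore"):
            means = np.nanmean(sub, axis=0)
        sub = np.where(observed, sub, means)
        X[mask] = sub
    values.loc[:, :] = X
    return ConcentrationTable(values)


def _ols_residuals(X: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(design, X, rcond=None)
    if rank < design.shape[1]:
        raise PreprocessError(
            "degenerate covariate design (age or BMI constant across samples)"
        )
    return X - design @ beta


def adjust_covariates(
    conc: ConcentrationTable,
    pheno: PhenotypeTable,
    scope: str = "pooled",
) -> ConcentrationTable:
    """Residualize each metabolite on intercept + age + BMI.

    ``scope="pooled"`` (default) fits one regression over all samples, so
    sex-specific correlation structure survives while linear age/BMI
    confounding is removed.  ``scope="by_sex"`` fits the regression within
    each sex separately.  Requires complete data (run imputation first).
    """
    if scope not in ("pooled", "by_sex"):
        raise ValueError(f"unknown adjust scope {scope!r}")
    conc, pheno = align(conc, pheno, min_group=4)
    values = conc.values.copy()
    X = values.to_numpy()
    if np.isnan(X).any():
        raise PreprocessError("covariate adjustment requires complete data; impute first")
    age = pheno.data["age"].to_numpy(dtype=float)
    bmi = pheno.data["bmi"].to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(age), age, bmi])
    if scope == "pooled":
        X = _ols_residuals(X, design)
    else:
        female = pheno.female_mask(conc.sample_ids)
        for mask in (female, ~female):
            X[mask] = _ols_residuals(X[mask], design[mask])
    values.loc[:, :] = X
    return ConcentrationTable(values)


def znormalize(conc: ConcentrationTable, sd_convention: str = "sample") -> ConcentrationTable:
    """Scale every metabolite to zero mean, unit standard deviation.

    ``sd_convention`` chooses the n-1 ("sample", default) or n
    ("population") denominator; Pearson correlations downstream are
    identical under either.  Zero-variance metabolites are rejected.
    """
    if sd_convention not in ("sample", "population"):
        raise ValueError(f"unknown sd convention {sd_convention!r}")
    values = conc.values.copy()
    X = values.to_numpy()
    if np.isnan(X).any():
        raise PreprocessError("normalization requires complete data; impute first")
    ddof = 1 if sd_convention == "sample" else 0
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        name = conc.metabolite_names[int(np.argmax(sd == 0))]
        raise PreprocessError(f"metabolite {name!r} has zero variance; cannot normalize")
    values.loc[:, :] = (X - X.mean(axis=0)) / sd
    return ConcentrationTable(values)


def preprocess(
    conc: ConcentrationTable,
    pheno: PhenotypeTable,
    adjust_scope: str = "pooled",
    sd_convention: str = "sample",
) -> ConcentrationTable:
    """Impute by sex, adjust for age and BMI, then z-normalize — in that order."""
    out = impute_by_sex(conc, pheno)
    out = adjust_covariates(out, pheno, scope=adjust_scope)
    return znormalize(out, sd_convention=sd_convention)
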
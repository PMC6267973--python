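"""Core tabular containers shared across the pipeline.

Concentrations are held as a samples x metabolites :class:`pandas.DataFrame`
with ``NaN`` marking missing measurements; phenotypes are a per-sample frame
with ``sex`` (``"female"``/``"male"``), ``age`` (years) and ``bmi`` (kg/m^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

_SEX_ALIASES = {
    "f": FEMALE,
    "female": FEMALE,
    "m": MALE,
    "male": MALE,
}


class DataValidationError(ValueError):
    """Raised when an input table violates the package's contracts."""


def normalize_sex(label: object) -> str:
    """Map a raw sex label (``F``, ``male``, ...) to the canonical form.

    Raises :class:`DataValidationError` for anything outside the
    female/male vocabulary.
    """
    key = str(label).strip().lower()
    if key not in _SEX_ALIASES:
        raise DataValidationError(
            f"unknown sex label {label!r}; expected one of female/male/F/M"
        )
    return _SEX_ALIASES[key]


@dataclass
class ConcentrationTable:
    """Samples x metabolites concentration matrix.

    ``values`` is indexed by sample id with one column per metabolite;
    missing measurements are ``NaN``.  Units are concentration-like (uM for
    a targeted MS panel) but never enter the math downstream.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataValidationError(f"duplicate metabolite names: {dups}")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def metabolite_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where a measurement is missing."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ConcentrationTable":
        return ConcentrationTable(self.values.copy())


@dataclass
class PhenotypeTable:
    """Per-sample phenotype frame with columns ``sex``, ``age``, ``bmi``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sex", "age", "bmi"} - set(self.data.columns)
        if missing:
            raise DataValidationError(f"phenotype table lacks columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample ids in phenotypes: {dups}")
        self.data = self.data.copy()
        self.data["sex"] = [normalize_sex(s) for s in self.data["sex"]]
        for col in ("age", "bmi"):
            try:
                self.data[col] = pd.to_numeric(self.data[col], errors="raise")
            except (ValueError, TypeError) as exc:
                raise DataValidationError(f"non-numeric {col} in phenotype table") from exc
            if not np.all(np.isfinite(self.data[col].to_numpy(dtype=float))):
                raise DataValidationError(f"non-finite {col} in phenotype table")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def sex(self) -> pd.Series:
        return self.data["sex"]

    @property
    def n_female(self) -> int:
        return int((self.data["sex"] == FEMALE).sum())

    @property
    def n_male(self) -> int:
        return int((self.data["sex"] == MALE).sum())

    def female_mask(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Boolean array (True = female) in the order of ``sample_ids``."""
        sex = self.data["sex"]
        if sample_ids is not None:
            sex = sex.reindex(sample_ids)
        return (sex == FEMALE).to_numpy()

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.data.copy())


def align(
    conc: ConcentrationTable, pheno: PhenotypeTable, min_group: int = 1
) -> tuple[ConcentrationTable, PhenotypeTable]:
    """Reorder phenotypes to the concentration-table sample order.

    Every sample must appear in both tables; each sex must have at least
    ``min_group`` samples.
    """
    conc_ids = set(conc.sample_ids)
    pheno_ids = set(pheno.sample_ids)
    if conc_ids != pheno_ids:
        only_conc = sorted(conc_ids - pheno_ids)[:5]
        only_pheno = sorted(pheno_ids - conc_ids)[:5]
        raise DataValidationError(
            "sample ids of concentration and phenotype tables differ "
            f"(concentration-only: {only_conc}, phenotype-only: {only_pheno})"
        )
    pheno = PhenotypeTable(pheno.data.reindex(conc.sample_ids))
    for sex, count in ((FEMALE, pheno.n_female), (MALE, pheno.n_male)):
        if count < min_group:
            raise DataValidationError(
                f"sex group {sex!r} has {count} samples; at least {min_group} required"
            )
    return conc, pheno
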
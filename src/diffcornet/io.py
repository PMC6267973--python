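"""CSV readers/writers and pipeline configuration.

Dialect: comma-separated UTF-8, ``.`` decimal, empty cell or ``NA`` for
missing.  Metabolite names may contain spaces (``PC aa C34:4``); pandas
quotes such fields as needed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ConcentrationTable, DataValidationError, PhenotypeTable
from .diffcorr import sort_edges

_NA_STRINGS = ("", "NA")


def read_concentrations(path) -> ConcentrationTable:
    """Read a samples x metabolites concentration CSV (first column = id).

    Empty cells and ``NA`` are missing; any other non-numeric cell raises
    :class:`DataValidationError` naming the sample and metabolite.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col].str.strip()
        is_na = cell.isin(_NA_STRINGS)
        num = pd.to_numeric(cell.mask(is_na), errors="coerce")
        bad = num.isna() & ~is_na
        if bad.any():
            sample = raw.index[bad.to_numpy().argmax()]
            raise DataValidationError(
                f"non-numeric concentration {cell[bad].iloc[0]!r} "
                f"for sample {sample!r}, metabolite {col!r}"
            )
        values[col] = num.to_numpy()
    return ConcentrationTable(values)


def read_phenotypes(path) -> PhenotypeTable:
    """Read the phenotype CSV (columns id, sex, age, bmi)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_concentrations(conc: ConcentrationTable, path) -> None:
    conc.values.to_csv(path, na_rep="NA", index_label="sample_id")


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, index_label="id")


def write_edges(edges: pd.DataFrame, path) -> None:
    """Edge table CSV, sorted by |r_diff| descending (ties by names)."""
    sort_edges(edges).to_csv(path, index=False, na_rep="NA")


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=list(_NA_STRINGS))


def write_node_metrics(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


_SCALES = ("half", "full")
_ADJUST_SCOPES = ("pooled", "by_sex")
_SD_CONVENTIONS = ("sample", "population")
_CLOSENESS = ("wf", "raw")
_MT_MODES = ("none", "bh")


@dataclass
class PipelineConfig:
    """Everything that determines a full pipeline run.

    When ``concentrations``/``phenotypes`` paths are ``None`` the run
    simulates its own input (the package's reference scenario) with the
    given panel geometry and ``seed``.
    """

    concentrations: str | None = None
    phenotypes: str | None = None
    n_metabolites: int = 168
    n_female: int = 140
    n_male: int = 96
    alpha: float = 0.05
    permutations: int = 1000
    seed: int = 0
    scale: str = "half"
    adjust_scope: str = "pooled"
    sd_convention: str = "sample"
    closeness_convention: str = "wf"
    multiple_testing: str = "none"
    top_k: int = 14
    outdir: str = "diffcornet_run"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        for value, allowed, name in (
            (self.scale, _SCALES, "scale"),
            (self.adjust_scope, _ADJUST_SCOPES, "adjust_scope"),
            (self.sd_convention, _SD_CONVENTIONS, "sd_convention"),
            (self.closeness_convention, _CLOSENESS, "closeness_convention"),
            (self.multiple_testing, _MT_MODES, "multiple_testing"),
        ):
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")
        if (self.concentrations is None) != (self.phenotypes is None):
            raise ValueError("provide both concentration and phenotype paths, or neither")

    @property
    def simulated(self) -> bool:
        return self.concentrations is None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(payload)


def derive_seeds(seed: int) -> tuple[int, int]:
    """Independent (simulation, permutation) seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)
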
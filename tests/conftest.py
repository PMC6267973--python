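import numpy as np
import pandas as pd
import pytest

from diffcornet.datatypes import ConcentrationTable, PhenotypeTable


def make_tables(values, sexes, ages=None, bmis=None, names=None):
    """Build aligned concentration/phenotype tables from raw arrays."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = [f"S{i + 1:03d}" for i in range(n)]
    names = names or [f"M{j + 1}" for j in range(m)]
    rng = np.random.default_rng(0)
    if ages is None:
        ages = rng.uniform(30, 70, n)
    if bmis is None:
        bmis = rng.uniform(20, 35, n)
    conc = ConcentrationTable(pd.DataFrame(values, index=ids, columns=names))
    pheno = PhenotypeTable(
        pd.DataFrame({"sex": list(sexes), "age": ages, "bmi": bmis}, index=ids)
    )
    return conc, pheno


@pytest.fixture
def small_dataset():
    """Complete 12-sample x 3-metabolite dataset, 8 female + 4 male."""
    rng = np.random.default_rng(42)
    values = rng.normal(10, 2, (12, 3))
    return make_tables(values, ["female"] * 8 + ["male"] * 4)
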
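"""Synthetic two-group metabolomics data with planted differential correlation.

The generator emulates a targeted mass-spectrometry panel (Biocrates-p180
style metabolite names, 168 metabolites by default) measured on two sex
groups (140 females, 96 males by default).  Each group's concentrations are
drawn from a multivariate normal whose correlation matrix carries planted,
group-specific entries; age and body-mass index act as linear confounders;
a configurable fraction of entries is removed completely at random.  The
planted pairs are returned as ground truth so downstream detection can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FEMALE, MALE, ConcentrationTable, PhenotypeTable

# Group demographics: mean and standard deviation of age (years) and BMI
# (kg/m^2) for the cohort the generator emulates.
FEMALE_AGE = (48.0, 12.6)
MALE_AGE = (51.0, 12.8)
FEMALE_BMI = (29.1, 5.5)
MALE_BMI = (28.9, 4.3)

#: eigenvalue floor used by the positive-semidefinite repair
PSD_FLOOR = 1e-8

_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val",
]
_ACYLCARNITINES = [
    "C0", "C2", "C3", "C3-OH", "C3:1", "C4", "C4-OH", "C5", "C5-OH",
    "C5:1", "C5-DC", "C6", "C6:1", "C7-DC", "C8", "C9", "C10", "C10:1",
    "C10:2", "C12", "C12-DC", "C12:1", "C14", "C14:1", "C14:1-OH",
    "C14:2", "C16", "C16-OH", "C16:1", "C16:1-OH", "C16:2", "C18",
    "C18:1", "C18:1-OH", "C18:2",
]
_BIOGENIC_AMINES = [
    "Creatinine", "Kynurenine", "Putrescine", "Sarcosine", "Serotonin",
    "Spermidine", "Spermine", "Taurine", "ADMA", "alpha-AAA",
]


def _panel_names() -> list[str]:
    """Master list of panel-style metabolite names (diacyl/acyl-alkyl
    phosphatidylcholines, lyso-PCs, sphingomyelins, acylcarnitines, amino
    acids, biogenic amines, hexose)."""
    names: list[str] = []
    names += _ACYLCARNITINES
    names += _AMINO_ACIDS
    names += _BIOGENIC_AMINES
    for c in range(24, 44, 2):
        for d in range(6):
            names.append(f"PC aa C{c}:{d}")
    for c in range(30, 44, 2):
        for d in range(5):
            names.append(f"PC ae C{c}:{d}")
    for c in (16, 17, 18, 20, 24, 26, 28):
        for d in (0, 1):
            names.append(f"lysoPC a C{c}:{d}")
    for c in (16, 18, 20, 22, 24, 26):
        for d in (0, 1):
            names.append(f"SM C{c}:{d}")
    names.append("H1")
    return names


@dataclass(frozen=True)
class PanelSpec:
    """Panel geometry: how many metabolites and how many subjects per sex."""

    n_metabolites: int = 168
    n_female: int = 140
    n_male: int = 96
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_metabolites < 2:
            raise ValueError("n_metabolites must be >= 2")
        # Fisher variance 1/(n-3) must be defined and positive.
        if self.n_female < 4 or self.n_male < 4:
            raise ValueError("each sex group needs at least 4 samples")

    def metabolite_names(self) -> list[str]:
        if self.class_labels:
            labels = list(self.class_labels)
            return [
                f"{labels[i % len(labels)]}{i // len(labels) + 1}"
                for i in range(self.n_metabolites)
            ]
        master = _panel_names()
        if self.n_metabolites <= len(master):
            return master[: self.n_metabolites]
        extra = [f"X{i + 1}" for i in range(self.n_metabolites - len(master))]
        return master + extra


@dataclass
class CorrelationScenario:
    """Correlation structure, confounding and missingness to simulate.

    ``planted_edges`` holds ``(i, j, r_female, r_male)`` tuples overriding
    ``base_corr`` (identity when ``None``) in the two groups.  ``age_effects``
    and ``bmi_effects`` are per-metabolite linear coefficients (concentration
    units per year / per kg/m^2) added after the correlated draw, so pooled
    linear residualization removes them exactly.  ``noise_sd`` is the
    metabolite-level standard deviation on the concentration scale; it
    rescales all metabolites alike and leaves correlations untouched.
    """

    base_corr: np.ndarray | None = None
    planted_edges: list[tuple[int, int, float, float]] = field(default_factory=list)
    age_effects: np.ndarray | float = 0.0
    bmi_effects: np.ndarray | float = 0.0
    missing_rate: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for i, j, rf, rm in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i},{j}) is a self-pair")
            for r in (rf, rm):
                if abs(r) >= 1:
                    raise ValueError(f"planted correlation {r} must satisfy |r| < 1")


@dataclass
class SyntheticDataset:
    """Generated concentrations, phenotypes, and the planted ground truth."""

    concentrations: ConcentrationTable
    phenotypes: PhenotypeTable
    truth: pd.DataFrame
    r_female: np.ndarray
    r_male: np.ndarray


def make_group_correlation(
    base_corr: np.ndarray,
    plants: list[tuple[int, int, float]],
    floor: float = PSD_FLOOR,
) -> np.ndarray:
    """Plant pairwise correlations into a base matrix and repair to PSD.

    The planted entries overwrite ``base_corr`` symmetrically.  If the
    result is indefinite its eigenvalues are clipped at ``floor``, the
    matrix is reconstructed and rescaled back to unit diagonal.  For plants
    that are jointly consistent the repair moves each planted entry by at
    most a few hundredths.
    """
    R = np.array(base_corr, dtype=float, copy=True)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("base_corr must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("base_corr must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("base_corr must have unit diagonal")
    m = R.shape[0]
    for i, j, r in plants:
        if not (0 <= i < m and 0 <= j < m) or i == j:
            raise ValueError(f"invalid planted pair ({i}, {j}) for {m} metabolites")
        if abs(r) >= 1:
            raise ValueError(f"planted correlation {r} must satisfy |r| < 1")
        R[i, j] = R[j, i] = r
    # Clip-and-rescale until the floor holds: restoring the unit diagonal
    # can nudge the smallest eigenvalue back under the floor slightly.
    for _ in range(100):
        w, V = np.linalg.eigh(R)
        if w.min() >= floor:
            return R
        w = np.clip(w, floor, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        R = (R + R.T) / 2.0
    raise RuntimeError("PSD repair did not converge")  # pragma: no cover


def one_factor_block_plants(
    center: int,
    partners: list[int],
    r_female: float,
    r_male: float = 0.0,
) -> list[tuple[int, int, float, float]]:
    """Planted edges for a differential module with a designated hub.

    The center correlates at ``r`` with each partner and the partners at
    ``r**2`` with one another (a single-factor block), which keeps the
    planted matrix positive semidefinite for any number of partners.
    """
    plants = [(center, p, r_female, r_male) for p in partners]
    for a in range(len(partners)):
        for b in range(a + 1, len(partners)):
            plants.append((partners[a], partners[b], r_female**2, r_male**2))
    return plants


def _factor(R: np.ndarray) -> np.ndarray:
    """Square root of a PSD correlation matrix via eigendecomposition."""
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def generate(
    spec: PanelSpec, scenario: CorrelationScenario, seed: int
) -> SyntheticDataset:
    """Draw one synthetic dataset.  Identical seed => bit-identical output.

    Females and males are sampled from multivariate normals with the
    repaired group correlation matrices; group demographics follow the
    configured age/BMI means and standard deviations; confounder effects
    enter additively; missingness is completely at random.
    """
    rng = np.random.default_rng(seed)
    m = spec.n_metabolites
    names = spec.metabolite_names()

    base = np.eye(m) if scenario.base_corr is None else np.asarray(scenario.base_corr)
    if base.shape != (m, m):
        raise ValueError(f"base_corr shape {base.shape} does not match {m} metabolites")
    Rf = make_group_correlation(base, [(i, j, rf) for i, j, rf, _ in scenario.planted_edges])
    Rm = make_group_correlation(base, [(i, j, rm) for i, j, _, rm in scenario.planted_edges])
    for name, R in (("female", Rf), ("male", Rm)):
        if np.linalg.eigvalsh(R).min() < -1e-10:  # pragma: no cover - repair guarantees PSD
            raise RuntimeError(f"{name} correlation matrix not PSD after repair")

    # Fixed draw order keeps the stream reproducible.
    zf = rng.standard_normal((spec.n_female, m))
    zm = rng.standard_normal((spec.n_male, m))
    age_f = rng.normal(FEMALE_AGE[0], FEMALE_AGE[1], spec.n_female)
    age_m = rng.normal(MALE_AGE[0], MALE_AGE[1], spec.n_male)
    bmi_f = rng.normal(FEMALE_BMI[0], FEMALE_BMI[1], spec.n_female)
    bmi_m = rng.normal(MALE_BMI[0], MALE_BMI[1], spec.n_male)
    baseline = rng.lognormal(mean=3.0, sigma=0.8, size=m)  # uM-like metabolite means
    miss = rng.random((spec.n_female + spec.n_male, m))

    Xf = baseline + scenario.noise_sd * (zf @ _factor(Rf).T)
    Xm = baseline + scenario.noise_sd * (zm @ _factor(Rm).T)
    X = np.vstack([Xf, Xm])
    age = np.concatenate([age_f, age_m])
    bmi = np.concatenate([bmi_f, bmi_m])

    beta_age = np.broadcast_to(np.asarray(scenario.age_effects, dtype=float), (m,))
    beta_bmi = np.broadcast_to(np.asarray(scenario.bmi_effects, dtype=float), (m,))
    X = X + np.outer(age, beta_age) + np.outer(bmi, beta_bmi)

    if scenario.missing_rate > 0:
        X = np.where(miss < scenario.missing_rate, np.nan, X)

    ids = [f"F{i + 1:03d}" for i in range(spec.n_female)] + [
        f"M{i + 1:03d}" for i in range(spec.n_male)
    ]
    conc = ConcentrationTable(pd.DataFrame(X, index=ids, columns=names))
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "sex": [FEMALE] * spec.n_female + [MALE] * spec.n_male,
                "age": age,
                "bmi": bmi,
            },
            index=ids,
        )
    )
    truth = pd.DataFrame(
        [
            {
                "i": i,
                "j": j,
                "metabolite_i": names[i],
                "metabolite_j": names[j],
                "r_female_true": Rf[i, j],
                "r_male_true": Rm[i, j],
                "delta_true": Rf[i, j] - Rm[i, j],
            }
            for i, j, _, _ in scenario.planted_edges
        ],
        columns=[
            "i", "j", "metabolite_i", "metabolite_j",
            "r_female_true", "r_male_true", "delta_true",
        ],
    )
    return SyntheticDataset(conc, pheno, truth, Rf, Rm)


def default_scenario(n_metabolites: int = 168) -> CorrelationScenario:
    """The reference simulation the pipeline examples and checks run on.

    Structure: a differential hub module (metabolite 0 with ten partners,
    one-factor r = 0.5 in females, absent in males), five disjoint pairs
    correlated only in males (r = 0.6, giving negative differential
    correlations), a sex-neutral "housekeeping" block (metabolites 40-59 at
    r = 0.35 in both groups, cancelling in the differential statistic), and
    mild age/BMI confounding on every metabolite.
    """
    if n_metabolites < 32:
        raise ValueError("default scenario needs at least 32 metabolites")
    base = np.eye(n_metabolites)
    hk = [i for i in range(40, 60) if i < n_metabolites]
    for a in range(len(hk)):
        for b in range(a + 1, len(hk)):
            base[hk[a], hk[b]] = base[hk[b], hk[a]] = 0.35
    plants = one_factor_block_plants(0, list(range(1, 11)), r_female=0.5)
    for k in range(5):
        i, j = 20 + 2 * k, 21 + 2 * k
        plants.append((i, j, 0.0, 0.6))
    conf_rng = np.random.default_rng(202300)  # fixed: scenario is a constant
    return CorrelationScenario(
        base_corr=base,
        planted_edges=plants,
        age_effects=conf_rng.normal(0.0, 0.015, n_metabolites),
        bmi_effects=conf_rng.normal(0.0, 0.03, n_metabolites),
        missing_rate=0.02,
        noise_sd=1.0,
    )
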
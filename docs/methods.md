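# Methods

## The model and its assumptions

`diffcornet` asks whether the pairwise association structure of a
metabolite panel differs between two groups of subjects (female and male
throughout the package, though nothing in the math is specific to sex).
For each unordered metabolite pair it computes within-group Pearson
correlations r_f, r_m and the statistic

    r_diff = c(n_f) · atanh(r_f) − c(n_m) · atanh(r_m),

with c(n) = √((n − 3)/2) under the default `scale="half"` convention.
atanh is the Fisher z-transformation, which makes a sample correlation
approximately normal with variance 1/(n − 3); the √((n−3)/2) weights give
each term variance ≈ ½, so r_diff is approximately standard normal when
both groups are uncorrelated. A `scale="full"` convention (c(n) = √(n−3))
is available; it doubles the variance of the statistic but not the
permutation p-values' validity, since those are computed from the
statistic's own permutation distribution. The choice of scale is recorded
in the run metadata because the two conventions change the magnitude of
every reported r_diff.

Two properties of this statistic are worth knowing:

- **Antisymmetry.** Exchanging every sample's group label negates r_diff
  exactly (bit-for-bit in IEEE arithmetic), because the two terms swap
  roles. The suite asserts this at 1e−12.
- **Centering bias for shared nonzero correlation.** Because each group's
  z is scaled separately, a pair with the *same* correlation ρ ≠ 0 in both
  groups has expected r_diff ≈ atanh(ρ)·(c(n_f) − c(n_m)), which is zero
  only when ρ = 0 or n_f = n_m. The statistic therefore "magnifies"
  differences but does not perfectly cancel shared structure at unequal
  group sizes. The permutation test absorbs this: under the null the
  labels are exchangeable and the permutation distribution of r_diff has
  the same offset, so the type-I error stays at the nominal level (the
  calibration study measures ≈ 5% at α = 0.05). The null-calibration
  check (mean ≈ 0, sd ≈ 1) is accordingly run at ρ = 0.

## Inference

Significance is by permutation: the sex labels of all samples are randomly
shuffled (group sizes fixed at n_f, n_m), r_diff is recomputed for every
pair, and the two-sided p-value is the add-one estimator
p = (1 + #{b : |r_diff_b| ≥ |r_diff_obs|})/(B + 1), never exactly zero.
B defaults to 1000. One seeded generator drives the whole permutation
stream; the seed is written to the run metadata. Labels are shuffled on
the *preprocessed* matrix — preprocessing is not re-run per permutation,
because re-imputing under shuffled labels would alter the data rather than
the labelling; the by-sex imputation step is therefore approximated under
the permutation null (exact when there are no missing values).

No multiple-testing correction is applied by default (the pipeline reports
raw p < α); Benjamini–Hochberg is available via
`select_significant(..., multiple_testing="bh")`. A two-sided
standard-normal p-value column (`p_normal`) is emitted for diagnostics
under the half scaling only; it is never used for selection.

## Network and key metabolites

Pairs with p_perm < α form a simple undirected graph whose edges carry the
sign of r_diff (positive = more correlated in females) and |r_diff| as
weight. Centralities are computed on the **unweighted** graph — the
definitions used are hop-count based, and |r_diff| is metadata, not a
distance:

- degree (DC): number of incident edges;
- betweenness (BC): fraction of all-pairs shortest paths through the node,
  normalized by (n−1)(n−2)/2;
- closeness (CC): (n_reach − 1)/Σd within the node's component, scaled by
  (n_reach − 1)/(n − 1) across components (Wasserman–Faust). This keeps CC
  comparable and sub-1 in disconnected networks, which differential
  networks typically are; the raw 1/Σd convention is available via
  `closeness_convention="raw"`.

Key metabolites are the union of the top-k nodes by each metric
(default k = 14, configurable): top-k by degree are labelled hubs, top-k
by betweenness or closeness bottlenecks. "High centrality" has no
canonical threshold; the top-k-union rule is this package's documented
convention. Ranking ties break by metric descending, then name ascending,
so reports are deterministic.

## Pre-processing

Order is fixed: (1) within-sex mean imputation of missing values,
(2) OLS residualization of each metabolite on intercept + age + BMI,
(3) z-normalization to zero mean, unit sd over the pooled sample.
Residualization is pooled across sexes by default: it removes linear
age/BMI confounding while leaving sex-specific correlation structure
intact (`adjust_scope="by_sex"` fits within groups instead). The exact
form of "covariate adjustment" is an open modelling choice; linear
residualization is the standard reading and is exactly correct under the
generator's additive confounding. Normalization uses the n−1 sd by
default (`sd_convention="population"` for n); correlations are invariant
to this. Correlations r = ±1 (e.g. duplicated columns) are clamped to
±(1 − 1e−7) before the z-transform rather than raising, so degeneracies do
not halt a run; zero within-group variance does raise, naming the
metabolite and group.

## Synthetic-data generator

The generator emulates a targeted-panel cohort: 168 metabolites with
Biocrates-style names, 140 female and 96 male subjects, age 48.0 ± 12.6 /
51.0 ± 12.8 years, BMI 29.1 ± 5.5 / 28.9 ± 4.3 kg/m² per group. Each
group's concentrations are multivariate normal around log-normal baseline
means with a configurable correlation matrix; planted pairs overwrite the
base matrix per group, and any indefiniteness is repaired by clipping
eigenvalues at 1e−8, reconstructing and rescaling to unit diagonal
(iterated until the floor holds). For *jointly consistent* plants the
repair moves planted entries by ≤ 0.05; an inconsistent set (e.g. a star
of many strong spokes) is repaired toward the nearest feasible structure,
which can move entries further — hub modules should therefore be planted
with `one_factor_block_plants` (center–partner r, partner–partner r²),
which is PSD by construction. Age/BMI confounding enters additively on
the concentration scale; missingness is completely at random at a
configurable rate (default scenario: 2%). Everything derives from one
seed; the same seed reproduces the dataset bit-for-bit.

The reference scenario (`default_scenario`) plants one female-only hub
module (center + 10 partners, r = 0.5), five male-only pairs (r = 0.6,
negative differential correlation), one sex-neutral block (20 metabolites
at r = 0.35 in both groups, which should cancel), and mild random age/BMI
coefficients fixed once (sd 0.015 and 0.03 per unit covariate on a
unit-sd concentration scale).

What the generator does **not** emulate: mass-spectrometry signal
processing, batch effects, limit-of-detection censoring, non-MCAR
missingness, non-Gaussian concentration distributions, or nonlinear
covariate effects. Passing tests on this generator demonstrate the
statistical machinery is correct under its stated model, not that real
cohort data meet that model.

## Numerical and design choices

- PSD repair floor 1e−8; repair iterates clip→rescale because restoring
  the unit diagonal can push the minimum eigenvalue marginally back under
  the floor.
- Permutation p-values use add-one (smallest reportable p is 1/(B+1)).
- Empty significant-edge sets build an empty network with a warning, not
  an error; mean degree is reported as 0 with an `empty` flag.
- Edge tables are written sorted by |r_diff| descending, ties by names;
  run directories are byte-identical for identical config + seed.
- CSV dialect: comma, UTF-8, `.` decimal, empty/`NA` missing; names with
  spaces are quoted as needed.

## Simulation-study sizes

The calibration studies (`diffcornet.calibration`, run by the test suite
and `scripts/acceptance.py`) use: 10,000 null pairs for the
null-distribution check; 200 null datasets of 10 metabolites at B = 200
for the type-I error; 100 replicates at B = 1000 for power against a
planted r_f = 0.8 / r_m = 0 pair; 50 replicates (30 metabolites, B = 200)
for hub recovery; 100 random graphs of ≤ 8 nodes against the brute-force
centrality oracle. These sizes put Monte-Carlo error comfortably inside
the asserted bands while keeping a full run in the tens of seconds.

## Known limitations

- The half/full scaling ambiguity is inherent to the statistic's
  definition in the field; both are implemented and the choice is logged.
- Pearson correlation only; no partial correlations or Gaussian graphical
  models, and no weighted-centrality variants.
- Mean imputation shrinks within-group variance slightly at high
  missingness; the default 2% rate makes this negligible.
- The permutation test assumes exchangeability of samples across groups
  under the null; strong covariate imbalance between groups would violate
  it (covariate adjustment mitigates, within its linear form).
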
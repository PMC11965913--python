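# Methods

## The data model

A phenotyping run produces a long table of measurements: one row per
(plant, timestamp), with the plant identified by a pot coordinate
`T:X:Y` (phenotyping table, x, y) and traits as numeric columns. Plants
are annotated through two side tables — a hand-made CSV mapping the
`V.T.R` plant ID (variety, treatment, repetition) to treatment and
cultivar labels, and a translation CSV that must be a strict bijection
between plant IDs and pot coordinates. An optional groups table attaches
extra factors per cultivar (e.g. the allelic state of a gene), letting the
analysis contrast genotype classes that cut across cultivars. Column names
are cleaned janitor-style (lowercase, non-alphanumerics → `_`) before
matching, and annotation values overwrite same-named archive columns.
Measurement rows whose coordinate has no translation entry are dropped
(the translation table defines which plants belong to the experiment);
factor levels are sanitized to `[A-Za-z0-9_]` because they end up in
letter displays and model formulas.

## Time clustering

Scanning all plants takes minutes, so the timestamps of one experimental
time point form a tight band (width ≈ the scan window) separated from the
next band by hours. We run DBSCAN on the one-dimensional time axis with
distance = absolute time difference, ε expressed in hours (default 1.0),
and minPts = 1. With minPts = 1 every point is a core point, so DBSCAN
degenerates to connected components under "gap ≤ ε" — an equivalence the
test suite verifies against an independent sort-and-split oracle on random
instances — and no measurement is ever discarded as noise. Higher minPts
is supported (isolated points are then labelled −1 and keep their own
timestamp) but is not the default because a lone measurement is still a
valid time point. Cluster ids are assigned in chronological order of
cluster start, and every member timestamp is replaced by the cluster
median (interpolated midpoint for even clusters, the pandas convention),
retained alongside the raw timestamp. Rows sharing (plant, cluster) are
technical replicates.

ε = 1 h assumes consecutive scans are ≥ 1 h apart and scan windows are
well under an hour; for protocols violating this the flag `--eps-hours`
adjusts it. Increasing ε can only merge clusters (verified as a
monotonicity property).

## Outlier screening

Within each (trait × time cluster) group — pooled over all plants, so the
screen sees the population spread at that time point — a value is blanked
if it lies more than `z_threshold` (default 3) sample standard deviations
from the group mean, or, in IQR mode, outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] with type-7 (linear-interpolation) quantiles.
Only the offending cell is blanked; the row's other traits survive.
Degenerate groups (n < 3 or zero spread) are never filtered. An optional
config key adds cultivar/treatment to the grouping key for experiments
where group means are so far apart that pooling would flag real biology.
On clean Normal data the 3σ rule retains ≈ 99.7% of cells; the IQR fences
are stricter on heavy-tailed data (both are measured by the acceptance
script rather than asserted as constants).

The filter runs after the logit transform (below) and before replicate
aggregation, i.e. on analysis-scale values, so a spike that would be
invisible on the bounded percentage scale is screened on the scale the
models use.

## Proportion traits and the logit

Spectral-index bins are percentages of scanned area and sum to 100 per
scan; bounded, skewed scales violate ANOVA's error model near 0 and 100.
Declared (or auto-detected: name contains "bin", values in [0, 100])
proportion columns are rescaled to (0, 1), exact 0s and 1s are replaced by
the nearest interior value observed anywhere in that column (a column with
no interior value is an error), and the logit ln(p/(1−p)) is applied. The
transformed column is renamed `<trait>_logit` so every downstream table
and export is explicit about the scale; the inverse transform is provided
for display.

## Replicate aggregation and factor cleanup

Technical replicates of one plant within one cluster collapse to the
median of surviving values (interpolated for even counts; all-blank groups
yield a missing cell), leaving one row per plant per time point. Factor
columns with a single distinct level are dropped — they carry no contrast
and would make the design matrix singular.

## Statistics

**Descriptives** per colon-joined group label: n, median, mean,
cv% = 100·sd/mean (sample sd), min, max, moment skewness m₃/m₂^{3/2} and
Pearson (non-excess) kurtosis m₄/m₂², the latter two reported missing for
n < 3 or zero spread.

**Model.** For response y and ordered user factors F₁…F_k the model is
y ~ F₁ + … + F_k + all two-way interactions (no higher orders — with
typical replication three-way cells are barely populated). Sums of
squares are sequential (Type I): each term's SS is the drop in residual SS
when it enters, its df the gain in model rank, computed from nested
least-squares fits. This makes the partition exact (Σ term SS + residual
SS = total corrected SS) on unbalanced and even partially aliased designs;
a term adding no rank is reported non-estimable and dropped with a
warning. Term order therefore matters and is the user's order. F is
meansq/residual meansq, p the upper F tail, significance codes
`***` < 0.001, `**` < 0.01, `*` < 0.05, `.` < 0.1. Missing responses are
dropped listwise; p-values are kept at full precision in all exports.

**Normality.** Shapiro–Wilk (scipy's Royston AS R94 implementation,
3 ≤ n ≤ 5000) is applied to the model residuals, not to raw groups, since
the ANOVA assumption is on errors; the W and p accompany every analysis.

**Tukey HSD.** All pairwise contrasts of a chosen term's observed level
combinations (interaction levels are colon-joined labels). The standard
error uses the *full model's* residual mean square with the Tukey–Kramer
form √(MSE/2·(1/nᵢ+1/nⱼ)); adjusted p-values and simultaneous 1−α
intervals come from the studentized range distribution with (k, residual
df). At k = 2 this reduces exactly to the pooled t-test (q = t√2), an
identity the acceptance suite checks. Note this differs from running an
isolated one-way Tukey per factor: the residual MS is taken from the model
that also absorbs the other factors.

**Letter display.** From the matrix of adjusted p-values, letters are
assigned by insert-and-absorb: start with all levels in one letter column;
for each significant pair occupying a common column, split it into two
copies, deleting one member from each; finally absorb columns whose
membership is a subset of another's. Letters are emitted a, b, c… ordered
by each column's earliest level. The construction guarantees the contract
— two levels share a letter iff their comparison is non-significant —
which is re-verified by brute force over random significance matrices.

## Synthetic experiments

The generator emulates the platform export end to end. Defaults: 3
cultivars × 2 treatments × 4 replicate plants (24 pots laid out 12 per
table), 3 scans at 8-hour spacing (the three-scans-daily cadence of
conveyor platforms), 2 technical replicates per scan, timestamps jittered
uniformly within a 330-second scan window. Morphological traits follow a
logistic growth curve plus additive factorial shifts expressed in units of
the residual sd (treatment step default 2σ, cultivar step 1σ) and Normal
noise (σ = 10 trait units); index bins are Dirichlet draws (geometrically
decaying concentration, first-bin concentration shifted by treatment so a
logit-scale effect exists) scaled to sum to 100. Planted outliers add
±`outlier_magnitude_sigma` × the *within-cluster* trait sd (noise plus
between-plant effect spread — the scale the pooled 3σ screen actually
operates on) to randomly chosen morphological cells, with flags recorded
in the ground truth. Everything is driven by one
`numpy` Generator, so a seed fixes the experiment byte-for-byte.

What the generator does not emulate: growth-curve heteroscedasticity,
spatial (pot-position) effects, missing scans, sensor drift, or occlusion
artifacts with temporal correlation. Passing tests therefore demonstrate
correctness of the pipeline's algebra and calibration under clean
factorial conditions, not robustness to every field artifact.

Problem sizes in the test and acceptance runs (oracle equivalence on
1,000 random instances, 500 random ANOVA fits, 200-seed identities and
recovery runs, 10 × 10,000-cell retention fixtures) were chosen as the
smallest designs at which the binomial/sampling error of each measured
rate is comfortably below its margin.

On recovery power: a 2σ shift with 10 plants per group observed once has
only ≈ 70% power at p < 0.001; observed at the design's three scan times
within the cluster+treatment model, power exceeds 99.9%, which is why the
recovery guarantee is stated (and measured) on the full repeated-scan
design.

## Determinism and caching

The processed table is cached as parquet with an embedded schema-version
marker and must round-trip exactly. Exported workbooks are byte-stable:
document properties are pinned and the XLSX container is repacked with
fixed entry dates, so identical inputs yield identical files across runs —
row order of the input does not matter either, since every statistic is
order-invariant (a tested property).

## Known limitations

- Type I SS only; no Type II/III, mixed models, or repeated-measures
  correlation structure (each plant contributes one value per cluster and
  clusters are treated as a fixed factor).
- No imputation: blanked outliers and missing traits propagate as missing.
- The IQR/3σ retention percentages on any real dataset depend on that
  dataset's tail behavior; the package asserts only the calibration
  properties above.
- Tukey p-values rely on the studentized-range distribution's numerical
  tails; agreement with reference implementations is to ~1e-3 in p.
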
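# Methods

This note documents the models, defaults and numerical choices behind
`admorph`, and what the synthetic cohort does and does not emulate.

## Volumetry and the label table

Volumes are hard voxel counts times the voxel volume taken from the NIfTI
header zooms; there is no partial-volume weighting because the inputs are
integer label maps, and no orientation handling because only counts
matter. The shipped table follows the Neuromorphometrics-style protocol:
138 labelled regions, 98 cortical (49 left/right pairs) and 40
non-cortical. Five non-cortical labels — left/right vessel, left/right
cerebral exterior, optic chiasm — are flagged `in_features=False`: their
raw volumes are still reported, but they enter neither the merged feature
set nor the surrogate aggregates. The protocol itself does not pin down
this exclusion set; it is carried as data (a CSV column), not code, and a
custom table can override it.

With that table the feature arithmetic closes exactly: 49 merged cortical
+ 21 merged non-cortical (14 pairs + 7 unpaired) + 8 hemisphere
exception features (left/right amygdala, hippocampus, inferior lateral
ventricle, lateral ventricle, which are informative enough to keep
unmerged) + 6 surrogates + age + gender = 86.

Surrogate membership follows the table's `tissue_class` column.
`BrainTissue` sums the cortical-GM, deep-GM, WM and `other` (brainstem,
cerebellum, vermis) classes; `Brain` additionally includes ventricular
and other CSF and is computed as one direct sum so that it is
bit-identical to the head-size covariate used by the nuisance model.

## Nuisance correction

Per feature, ordinary least squares of the raw volume on age (years),
gender (0 = female, 1 = male), and head size, fitted on healthy controls
only, with the head size approximated by total brain volume (sum of all
structures). The full predicted component — intercept included — is
subtracted from every subject, so corrected values are deviations from
the control norm of matched age/gender/size, and the control mean of
every corrected feature is zero to machine precision. The `Brain`
feature is exempt (correcting it against itself is degenerate by
construction) as are the age/gender covariates; the exemption set is
explicit configuration. Longitudinal change rates are never corrected —
correction applies to cross-sectional volumes only. Plain single-pass
OLS, no robust or regularized variants. The four hemisphere exception
features use total (not hemispheric) brain size as their size covariate.

A consequence of the sum-of-structures size approximation worth knowing:
if data were generated from a latent head size *H*, regressing on the
realized sum (a noisy affine function of *H*) attenuates the recovered
slopes. Parameter-recovery checks therefore fit against the generating
head-size column that the synthetic subject table exposes; against the
sum, recovery is biased by construction, which is a property of the ICV
approximation, not a defect of the fit.

## Group statistics

Cohen's d uses the absolute mean difference over the (n−1)-weighted
pooled SD. The t-test is the pooled-variance Student test (not Welch):
recomputing from published two-group summaries reproduces printed
p-values under pooling. The raw-data paths delegate to the summary paths
so the two agree exactly. Significance codes follow o / + / ++ for
n.s. / p < 0.05 / p < 0.001 (strict inequalities); the Bonferroni variant
divides both thresholds by the family size, default m = 84 (the
volumetric features; age and gender are not tested). Both the family
size and whether the 0.001 threshold is divided are configurable, since
conventions differ.

## Classification harness

Stratified 6-fold cross-validation (stratification chosen because group
sizes are imbalanced), reshuffled per run, predictions pooled over the
folds of a run, metrics per run, mean over runs. Defaults: 100 runs for
single-feature LDA, 20 for SVM/RF. The SVM is linear-kernel with C = 1
and per-feature min-max rescaling to [0, 1] fitted on the training folds
only (a held-out sample can map outside [0, 1]; no leakage). The random
forest uses 100 trees. The positive class is the diseased group; bACC =
(SENS + SPEC)/2 is prevalence-invariant. One seed drives both fold
shuffles and forest bootstraps. No attempt is made to reproduce
published classifier accuracies numerically — those depend on the real
cohort — so the harness is validated by properties: perfect separation on
well-separated Gaussians, chance level on permuted labels, exact metric
definitions against counting oracles.

## Atrophy rates and sample sizes

Rates are stored on the log scale only, 100·ln(v₂/v₁) %, making them
anti-symmetric under visit swap and exactly additive over chained
intervals; a positive rate is volume increase. Pairs with a missing
visit are dropped, never imputed. Sample size follows
N = (z₁₋β + z₁₋α/2)² · 2σ_g²/Δ² with defaults effect fraction 0.25,
power 0.80, α 0.05. Two z conventions: `paper` (0.84, 1.96, the
two-decimal values conventional in the trial-design literature; default,
reproduces published tables) and `exact` (normal quantiles 0.8416,
1.9600). Rounding is to nearest by default (matches published tables);
ceiling is available since trial design usually rounds up. The
normal-aging correction sets Δ = 0.25·(μ_g − μ_healthy), assuming
σ_healthy ≈ σ_g, which is usually more conservative. Note that
recomputing published corrected sample sizes from one-decimal printed
rates is well-conditioned only where |μ_g − μ_healthy| is large relative
to the 0.05 rounding grain; for small-rate structures (brain tissue,
white matter, deep GM) the printed precision leaves N uncertain by tens
of subjects.

## Cohort stratification

Trajectories are labelled deterministically: reverters (any step to a
less severe stage) excluded; baseline EMCI/SMC excluded; baseline MCI
converting to AD within 24 months → pMCI, later → excluded (late
converter); baseline MCI still MCI at ≥ 24 months and at the last
available diagnosis → sMCI, otherwise excluded (insufficient follow-up);
baseline HC converters keep the HC label cross-sectionally but are
flagged out of longitudinal analyses. The two-year cut is compared with
a ± 3-month window (configurable) to absorb visit-scheduling jitter.
Every subject receives exactly one label, and every exclusion carries an
enumerated reason.

## Synthetic cohort

Head size is drawn first (Normal, mean 1.2 × 10⁶ mm³, SD 1.1 × 10⁵) and
all structures are generated conditionally on it, mirroring the
size-as-covariate design. Baseline volume per label: intercept + linear
age/gender/size terms + group offset + Gaussian noise; non-positive
draws are resampled, not clipped, so configured SDs are preserved.
Follow-up volumes apply a per-interval log-scale rate draw, so they are
positive by construction. Gender is 0 = female / 1 = male everywhere.

Defaults (the shipped `default_cohort.yaml`) set group sizes 404 HC /
166 sMCI / 177 pMCI / 322 AD, ages uniform on [55, 90], P(male) = 0.543.
Amygdala, hippocampus, inferior lateral ventricle and entorhinal labels
are anchored to published per-hemisphere offsets and SDs; every other
label gets tissue-class-level relative offsets (e.g. cortical GM −4.6%
of its reference volume in AD, ventricles +46%) with sMCI/pMCI offsets
scaled by 0.33/0.86 of the AD offset (the ratios observed for the
amygdala). Volume-change means/SDs per group and interval are anchored
per structure where published (hippocampus, ventricles, medial temporal
gyrus, entorhinal area, …) and per tissue class otherwise.

What the generator does **not** emulate: covariances among structures
(independent given head size — real regional atrophy is correlated, so
synthetic all-feature classifiers are optimistic), scanner/site effects,
non-Gaussian and age-dependent atrophy distributions, and missing
follow-ups. Because labels are independent, surrogate aggregates built
by summing ~100 labels have much smaller relative SDs than real
aggregates; tests that pass on synthetic data therefore validate the
*machinery* (definitions, invariances, leakage-freedom, determinism),
not expected real-data accuracy levels.

## Report layer and problem sizes

Reports are TSV with fixed column order; floats are formatted at
published precisions (d to 3 d.p., classification metrics to integers,
rates to 1 d.p.) only at the report layer — full precision is kept
internally. All randomness flows from one run seed through named stage
seeds (CRC-mixed `SeedSequence`), so a rerun of the same config is
byte-identical. The default end-to-end run reports the six surrogates
plus the ten largest-effect individual structures per contrast, with 10
LDA runs and 5 SVM/RF runs per table — enough for stable means at
synthetic effect sizes while keeping a full run under a minute on one
CPU; library-level defaults remain 100/20 runs.
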
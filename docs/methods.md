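# Methods

This note documents the modelling assumptions, parameter defaults and
numerical conventions of `tabletpred`, and states what the synthetic
test bed does and does not demonstrate.

## Mixture descriptors

Material-level scalar properties are aggregated to the mixture level
by the composition-weighted sum `p_mix = Σ xᵢ pᵢ`. This is a practical
linear approximation for building features, not a physical interaction
model: real powder blends show nonlinear interactions (percolating
lubricant films, ordered mixing of fines), but with the sample sizes
typical of early development data a nonlinear mixture model would add
dimensionality faster than information. The rule is linear in both the
composition and the property matrix, so every mixture descriptor lies
inside the convex hull of its component values — a useful invariant
that the test suite checks by property-based testing.

Ordinal scores (solubility, lipophilicity, flowability) are mixed by
the same rule. Treating ordinals as interval-scaled is a modelling
choice; the alternative (category-level indicator features) is not
implemented.

Missing scalar properties are imputed before mixing with a
k-nearest-neighbour mean (k = 5): distances are Euclidean over
mutually observed, column-standardized properties, neighbour ties
break deterministically by material id, and fewer than k usable
neighbours fall back to all available ones (with a warning). Materials
data are small (tens of rows), so the imputer is written directly
rather than through a library transformer — it must honour the
mutually-observed-columns convention and the deterministic tie-break.

## Per-target descriptor profiles

Which descriptors enter which target's block is configured in
`src/tabletpred/data/target_profiles.yaml`. The shipped defaults give
block widths hardness 44, disintegration time 45, flow function 37,
cohesion 37, thickness 43:

* all targets: the five basic powder properties (densities, CI, HR,
  loss on drying) plus the 9 category ratios and 21 interaction terms;
* flow function / cohesion: + FLODEX and the flowability score
  (7 scalars + 30 = 37);
* thickness: all nine scalars + the four geometry/stress features
  (9 + 4 + 30 = 43);
* hardness: thickness profile + `pressure × (1/weight)` (44);
* disintegration time: hardness profile + `loss-on-drying ×
  solubility` (45).

The two product features are reconstructions chosen for mechanistic
plausibility — compaction stress per unit fill mass modulates bonding
(hardness), and the moisture–solubility interaction modulates water
uptake (disintegration) — and to keep the printed widths exact. Teams
with their own data should treat the profiles as a versioned config,
not a ground truth.

## PSD handling

PSDs live on a shared 80-point geometric grid from 0.115 to 5000 µm
(log-uniform spacing is the natural choice for laser-diffraction
data). Mixture PSDs use the same composition-weighted rule; materials
without a PSD contribute a zero vector and the mixture is renormalized
so the non-missing mass sums to one (an error is raised only when no
component has a PSD — the mixture distribution is then undefined).

Summary conventions (all exposed through `PSDSummaryOptions`):

* quantiles interpolate the cumulative mass linearly in log-diameter
  (PSDs are log-scaled); a point mass returns its own diameter for all
  quantiles;
* moments are frequency-weighted arithmetic moments in linear diameter
  (µm); a log-diameter variant is available. A degenerate distribution
  (std = 0) defines skewness and kurtosis as 0;
* kurtosis is excess kurtosis (normal ⇒ 0);
* the 25 µm and 150 µm threshold fractions are inclusive and evaluated
  at grid points (no sub-bin splitting);
* entropy is −Σ p ln p in nats, bounded by ln 80 ≈ 4.382.

## Feature sets and preprocessing

MP concatenates the material addition-rate columns (one per material,
lexical order), five numeric process settings (compaction force,
tablet diameter, target weight, curvature radius, fill depth) and the
punch-type category — with two punch levels the encoded width for a
151-material library is 151 + 5 + 2 = 158. MPD appends the per-target
descriptor block; MPDD appends the ten PSD summaries.

Preprocessing is strictly leakage-safe: one-hot category lists and
standardization means/sds are fitted on training rows only and applied
as pure functions. Addition-rate columns are never standardized (they
are already on a common [0, 1] scale and their sparsity pattern is
meaningful); all other numeric columns are standardized, with
zero-variance columns mapping to zero. Punch categories unseen at
application time encode as all-zero dummies with a warning —
consistent with refit-free application.

## Models

Five classical learners are tuned by exhaustive grid search on Dev
RMSE over fixed reference grids (ET and RF 108 points, SVR the full
5×2×3 = 30 cross-product even though γ is inert for the linear
kernel, PLS 10, Lasso 5); ties keep the first point in documented
iteration order, and PLS points with more components than features
are skipped with a warning.

The neural network is a multi-branch MLP written in numpy: the
descriptor and PSD blocks pass through their own hidden stacks, are
concatenated with the raw materials+processes block, and feed joint
hidden layers ending in a linear unit. Training is mini-batch Adam on
MSE with inverted dropout, early stopping on Dev RMSE (patience 20,
best weights restored) and learning-rate halving after a 10-epoch
plateau; the patience and decay constants are implementation choices.
Hyperparameters (log-uniform learning rate 1e-5–1e-2, four
activations, dropout 0.1–0.5, 1–3 layers of 10–190 units per stack,
batch 8/16/32, 50–300 epochs) are searched by a fully seeded random
search scored on Dev RMSE; trials with non-finite losses are marked
failed and skipped. Random search is a deliberate design choice: the
space is low-dimensional, every contract (fixed trial budget,
determinism, best ≤ median) holds, and it has no sampler state to
version.

When the pipeline runs without a search (the "desk-scale" mode used
by the orchestration helpers and the acceptance script), each family
uses the midpoint of its reference grid — e.g. Extra Trees with 100
trees, max_features 0.5, min_samples_leaf 5. Mid-grid leaves matter:
fully grown trees interpolate target noise, which both inflates
variance and distorts paired feature-set comparisons (extra irrelevant
columns then act as tree-decorrelating regularization and can shift
the paired improvement away from zero even when the added features
carry no signal).

Tree-ensemble feature importance uses decision-path attributions: for
each sample the change in node mean along the decision path is
credited to the split feature, so the per-feature contributions plus
the root baseline reproduce the prediction exactly (local accuracy,
checked to 1e-6 in the tests). Mean absolute contributions are
averaged over the refits from repeated seeds. Decision-path credit is
order-dependent (it conditions on the path taken), which is the main
difference from Shapley-style axiomatics; it requires no background
set and is exact and fast for the ensembles used here.

## Interpolation protocol

Repeated random 5:3:2 Train/Dev/Test splits (floor rounding on train
and dev, remainder to test), models tuned on Dev and refitted on
Train+Dev, scored on Test by R² and RMSE. R² on a constant test
target is undefined; the implementation returns NaN with a warning
rather than raising, so the (still valid) RMSE is preserved.

The paired improvement d = RMSE(MP) − RMSE(augmented) is matched
strictly by (model, seed); unpaired results are dropped with a
warning. Summaries: mean d̄ with a percentile bootstrap CI
(B = 50,000, seeded independently of the split seeds), a two-sided
Wilcoxon signed-rank test (zeros removed; exact null for n ≤ 25
without ties, else normal approximation with tie correction; reported
without multiplicity correction), and directional agreement between
disjoint discovery/validation seed halves (default registry: seeds
0–24 / 25–49) with an exact Clopper–Pearson interval. A mean
improvement of exactly zero counts as agreement only with another
exact zero — vanishingly rare with continuous metrics.

## Extrapolation protocol

Rows are ordered by `time_index` (file order, with a warning, when the
column is absent). The rolling-origin plan fixes Dev and Test widths
at round(0.2 n) and round(0.1 n) and expands the training window from
round(0.5 n) in four 5% steps — five folds, nested training windows,
strict temporal causality. The NN is excluded from the default
extrapolation family list: with only five folds its training variance
dominates the fold means.

Applicability-domain indicators are fitted per fold on Train+Dev only:

* leverage: hat values of the intercept-augmented linear model
  (pseudo-inverse for rank deficiency), threshold at the 95th
  percentile (linear-interpolation convention — fitting-set coverage
  is then ≈ 95% by construction, which the tests pin down);
* Mahalanobis: squared distance in the PCA subspace retaining ≥ 95%
  variance, chi-square 0.975 threshold on the component count (both
  constants are config arguments; they are conventional, not
  canonical);
* kNN: mean Euclidean distance to the k = 5 nearest fitting rows
  (self-distances excluded), 95th-percentile threshold;
* range: inclusive per-feature min–max bounds.

Covariate shift is quantified per feature as Jensen–Shannon divergence
with base-2 logs (bounded in [0, 1], symmetric): 20 quantile bins of
the pooled non-missing values, additive smoothing 1e-6,
renormalization, computed per fold between Train+Dev and Test and then
fold-averaged; the headline summary is the mean of the top-10
fold-averaged values. PSI on the same bins is a secondary output.
Binning, smoothing and log base are reconstructions — documented
defaults, not claims of uniqueness.

## Synthetic test bed

The generator emulates the schema and scale of an early-development
formulation database. Conditions (chosen once; all randomness flows
from one master seed through named substreams):

* materials: 8 diluents, 9 disintegrants, 4 polyols, 4 lubricants,
  2 binders, 2 glidants (29 total); scalar properties from truncated
  normals around per-category means, with CI/HR derived from the drawn
  densities so the table is internally consistent; PSDs are
  two-component lognormal mixtures on the shared grid; 10% of scalar
  entries and 15% of PSDs are censored;
* formulations: per-category share templates with Dirichlet
  perturbation, renormalized; compaction force uniform in
  4400–19,600 N; two punch types; diameters {8, 10, 12} mm; weights
  0.25–0.60 g; sequential time index;
* targets: documented closed forms plus Gaussian noise (hardness
  sd 8 N; disintegration time multiplicative lognormal sd 0.12; flow
  0.8; cohesion 0.05 kPa; thickness 0.02 mm). Hardness rises with
  compaction pressure and a quadratic in the mixture Hausner ratio;
  disintegration time is exponential in a hardness surrogate minus
  disintegrant ratio and fine fraction (strictly positive and strictly
  monotone by construction); flow falls and cohesion rises with the
  fine fraction; thickness follows fill mass over an effective
  density. All coefficients and noiseless values are returned for
  recovery tests.
* null mode: every target is a linear function of fill depth alone — a
  process setting present in MP from which no descriptor or PSD
  summary is derived — so the augmented blocks are pure nuisance by
  construction;
* drift mode: after an onset (default 0.6 of the stream) a reserve
  disintegrant unused before onset enters compositions and the
  category balance tilts, both ramping linearly to the end of the
  stream. The ramp (rather than a step) emulates progressive
  formulation renewal: the newest rows are always the most novel, so
  expanding-window thresholds cannot silently absorb the shift.

What passing tests on this bed show: the plumbing is correct, the
statistics are calibrated on their own terms, descriptor augmentation
is detected when the response truly routes through a mixture
descriptor, and drift is flagged by leverage coverage and JSD. What
they do not show: anything about real formulation data — the generator
has no batch effects, no measurement-protocol changes, no correlated
missingness, linear-plus-noise surfaces far smoother than real
compaction physics, and far fewer unique materials than a mature
database.

One calibration caveat is worth stating explicitly. The bootstrap CI
for d̄ resamples split seeds within one fixed dataset, so its error
budget covers split-to-split variation only. Across freshly generated
null datasets, small dataset-specific effects remain (chance
correlations between the fixed descriptor columns and the fixed noise
realization, exploited consistently by tree ensembles across splits
— below 1% of the target RMSE here), and the CI will legitimately
exclude zero for some datasets. Fixed-dataset inference should not be
read as a statement about the population of datasets.

## Problem sizes

The shipped tests and the acceptance script use deliberately modest
sizes — 600 formulations and 10–20 split seeds for effect-size runs,
300 rows for drift diagnostics, 20 replicates for calibration — which
keep a full run in the low minutes on one CPU while leaving every
qualitative conclusion stable under the stated seeds.

## Known limitations

* The linear mixture rule ignores component interactions by design.
* Ordinal scores are mixed as if interval-scaled.
* Decision-path attributions are path-conditional, not Shapley values.
* The per-target descriptor profiles are a documented reconstruction.
* The NN is a compact reference implementation; it is not performance-
  tuned and is excluded from extrapolation aggregation by default.
* AD indicators flag coverage, not error: association between
  indicator values and realized errors is weak and heterogeneous, and
  they should be used as risk flags alongside monitoring, not as error
  predictors.
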
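# Methods

This note documents the statistical procedures implemented in `metabscreen`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Data model

A `FeatureTable` is an intensity matrix over samples × features.  Features
are named `<Rt>_<mass><kind>` (retention time in minutes to 2 decimals, mass
in amu to 4 decimals; kind `m/z` for adduct masses, `n` for deconvolved
neutral masses).  Samples carry a role — `study`, `qc` (pooled quality
control), `blank` (solvent), `mix` — and study samples carry a binary
case/control label.  Missing values are NaN; by default a literal `0` in an
input file is read as missing, because peak-table exports commonly write 0
for undetected peaks and the downstream imputation assumes below-detection
missingness.  This is a config switch (`DialectConfig.zero_is_missing`).

## Preprocessing chain

The composite `preprocess` applies, in this order and no other:

**filter → impute → PQN → sqrt → center → Pareto → (outlier screen)**

* **Filtering.** A feature is *included* if more than 95% of its blank
  entries are missing, or if the ratio (5th percentile over QCs)/(95th
  percentile over blanks) exceeds 5; it is then *excluded* if its QC
  coefficient of variation exceeds 20%.  Percentiles are
  linear-interpolation (type-7) quantiles over present values.  The CV uses
  the sample (n−1) SD on raw, pre-normalization intensities — the scale on
  which instrument repeatability is usually quoted.  A feature with fewer
  than two present QC values cannot demonstrate repeatability and is
  excluded.  When every blank value is missing the ratio is left
  unevaluated (the first rule already includes the feature), which avoids a
  0/0.  QC and blank rows are dropped after filtering.
* **Imputation.** Each missing study entry is replaced by an independent
  uniform draw on (0, min), where min is the feature's smallest present
  study intensity.  This low-value imputation matches left-censored
  (below-detection) missingness; it runs before normalization so that the
  imputed values are on the measured scale.  Draws come from one seeded
  stream (row-major cell order), so results are bit-reproducible.
* **PQN.** The reference spectrum is the QC median when at least three
  complete QC spectra exist, else the study median (config-overridable; an
  explicit reference vector is also accepted).  Each sample is divided by
  the median of its feature-wise ratios to the reference; the quotients are
  returned for audit, because on urine data they estimate relative dilution.
* **Transform/scale.** Square root, then mean centering and Pareto scaling
  (divide by √SD) with statistics computed over the study samples only.
  Constant columns are left as zeros and flagged rather than dropped.
  Pareto identity: after scaling, each column's variance equals its
  post-sqrt SD.
* **Outlier screen.** PCA per outcome group on the scaled matrix, with the
  component count A the smallest reaching 80% cumulative variance (capped at
  min(n−1, 10)).  Hotelling T² on the scores uses the in-model limit
  T² ≤ (n−1)²/n · Beta₁₋α(A/2, (n−A−1)/2) — the new-observation F limit is
  badly conservative for training samples, whose leverage-shrunk T² follows
  the Beta law; the Beta form calibrates at the nominal α (measured ≈5% at
  α = 0.05 on multivariate-normal nulls).  DModX is the normalized
  orthogonal-residual SD with an F approximation on (p−A, (p−A)(n−A−1))
  degrees of freedom.  The screen flags; it never removes samples — removal
  is an analyst decision.

## Univariate screen

Per feature, case vs control on the preprocessed scale:

* Shapiro–Wilk in each group; the **normality gate** passes iff p > 0.10 in
  both.  Constant vectors fail the gate by convention.
* Welch t-test (unequal variances — the safer default; pooled is a switch)
  where the gate passes; two-sided Mann–Whitney always (exact enumeration
  for tie-free groups of ≤8, tie-corrected normal approximation otherwise).
* **Storey q-values** with fixed λ = 0.5:
  π̂₀ = #{p > λ}/(m(1−λ)) capped at 1, q(i) = min over the tail of
  π̂₀·m·p(j)/rank(j).  FDR is computed per test family: the t family over
  gated features only, the MW family over all features.  The reported
  selection is the features at q < 0.15 in *both* families, sorted by
  ascending t-test p — features failing the gate can never enter it.
* Rank-based AUC (case positive, half-credit for ties) with the
  Hanley–McNeil 95% CI; "significant AUC" means the CI excludes 0.5.  AUC is
  reported unoriented (it may fall below 0.5) with the direction of effect
  carried separately.
* Cross-cohort intersection matches by exact formatted id by default, or by
  tolerance (rt ± 0.02 min, mass ± 5 ppm, same mass kind) on request;
  many-to-many tolerance matches are an error, not a guess.

## VIP-based PLS-DA stability selection

PLS-DA is PLS1 regression (NIPALS with sequential deflation) against the
centered ±1 response.  Weights are unit-norm; the per-component sign is
fixed by making the largest-magnitude weight entry positive.  VIP is
normalized so Σⱼ VIPⱼ² = p.

The VIP cut-off is data-driven: for each threshold in a grid bracketing the
conventional cut of 1.0 ({0.6, 0.7, …, 1.6} by default), the features at or
above the threshold (VIPs from the full-subsample model) define a refit
whose 7-fold cross-validated R² (Q² = 1 − PRESS/TSS, negative allowed) is
maximized jointly over the threshold and the component count A ≤ 5.  Ties
break toward the larger threshold (sparser model).  Folds are deterministic
stratified round-robin assignments, so the whole search is reproducible
without auxiliary randomness.  A is capped automatically by what the
training folds can support.

The stability wrapper draws, per model, floor(0.75 · n_case) cases and the
same number of controls without replacement (100 models by default), runs
the threshold search on the subsample, and counts surviving features.  The
stable set is features selected in strictly more than 50% of models (an
inclusive `freq_inclusive` switch exists, since a ≥50% reading is also
defensible).  Each model is evaluated only on the samples it never saw:
AUCpred from the continuous PLS prediction (LDA posterior ranking is a
config alternative), and a confusion matrix from LDA on the model's score
space (pooled covariance, empirical priors, ridge 1e-6 fallback on a
singular pooled covariance, boundary ties to control).

Two caveats the tests make explicit.  The per-model Q² that drives the
threshold choice is computed *after* the VIP cut was chosen on the whole
subsample, so it is optimistic (selection bias); it is a model-selection
score, not a performance estimate.  And because subsamples share most of
their observations, a feature whose spurious correlation with the outcome is
a property of the particular dataset can be selected consistently across
models — the stable set under a global null is therefore not reliably
empty.  Held-out AUCpred carries the honest performance signal: it is
computed exclusively on never-trained samples and sits at chance (0.5) under
the null.

## Balanced random-forest evaluation

Training sets of floor(0.70 · min(group sizes)) per class — floor, which
reproduces the printed sizes 14+14 from a 20/151 split and 34+34 from
49/112 — feed one forest per replicate (500 replicates × 500 trees by
default, Gini splits, min(40, p) candidate variables per split, bootstrap
resampling within the training subset; switchable off).  Every sample not
drawn is a test sample; the held-out error (per class and total, the total
being the label-weighted combination) is recorded after each cumulative tree
count with even-vote ties going to control.  Forests are scikit-learn
classifiers behind this module's surface; the subsampling, cumulative-vote
curves and percentile summaries are this package's own.

## Synthetic generator

The generator emulates the structure the analysis assumes: per feature a
baseline log-mean μⱼ ~ U(6, 12) (intensities ~4·10²–1.6·10⁵), a shared
log-SD σ = 1; per study sample a dilution factor dᵢ = exp(N(0, τ²)) with
τ = 0.3 (a realistic spread of urine concentration); planted features
shifted by ±δ log-units in cases (default δ = 1.5, 20 of 1555 features;
default cohort shape 20 cases/151 controls); left-censoring of each
feature's lowest `missing_rate` = 20% of study intensities; QC replicates
from the pooled mean spectrum with multiplicative noise at CV = 10% and no
censoring; blanks missing with probability 0.98, otherwise background two
orders of magnitude below the study median.  Retention times are uniform on
[0.5, 7.0] min and masses on the 20–1200 amu acquisition window.

Deliberately not emulated: chromatographic drift, batch/injection-order
effects, and adduct/isotope correlation between features — features are
independent.  Passing tests therefore demonstrate correctness of the
procedures and their calibration under this model, not statistical power on
real data, where correlated features and weaker effects will lower recovery
rates and raise the FDR of any selection.

## Problem sizes in tests and the acceptance script

Monte-Carlo tests use the smallest sizes at which the checked property is
stable (e.g. 300 features × 160 samples for stability-selection recovery,
10–50 seeds per claim).  The acceptance script runs two cohort-shaped
analyses (171 and 161 samples, 500 features, 100 stability subsamples,
forests scaled to 50 replicates × 100 trees) plus a signal-free control —
sizes chosen so a complete from-scratch rerun stays around a minute while
every stage still operates in its intended regime.

## Known limitations

* Storey's π̂₀ uses a single fixed λ; the smoother-based estimator is out of
  scope.
* The Mann–Whitney exact path is only used for small tie-free groups; all
  cohort-scale p-values use the tie-corrected normal approximation.
* DModX critical values rest on an F approximation whose degrees of freedom
  are themselves approximate; the screen is a flagging aid, not a test with
  exact level.
* Stability-selection counts carry no finite-sample false-selection bound;
  the >50% rule is a frequency heuristic (see caveats above).
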
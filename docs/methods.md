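# Methods

This note records the models behind `breathpanel`, the assumptions they
make, the defaults that matter, and the places where the design was
genuinely open and a choice had to be made.

## Synthetic cohort model

The generator emulates a two-center, FIT-positive screening cohort at
colonoscopy: 30 CRC, 138 AA, 130 NAA and 84 negative controls (382
samples) by default, with `n_features = 200` VOC peak-table features.

For sample *i* (class *c*, batch *b*) and feature *j* the latent model is

    log A_ij = mu_j + beta_j(c) + gamma_bj + delta_bj * eps_ij

* `mu_j ~ N(9, 1)` — baseline log peak area (arbitrary instrument units;
  e^9 ≈ 8·10^3 is a typical integrated-area magnitude).
* `beta_j(c) = sign_j * effect_sizes[c]` for the 10 planted markers, zero
  otherwise. Defaults: full effect 1.0 (natural-log units, i.e. ≈ e-fold)
  in AA and CRC, half effect 0.5 in NAA, zero in controls; signs alternate
  (+1 = elevated in AA). No published effect sizes exist for breath VOCs in
  this population, so these are calibration choices: 1.0 log-unit against
  `noise_sd = 1.0` gives per-marker standardized effects of d ≈ 1, i.e.
  individually informative but far from trivially separable — the regime
  in which panel selection is actually exercised.
* `gamma_bj ~ N(0, 0.3)`, `delta_bj = exp(N(0, 0.2))` — per-batch,
  per-feature location and scale instrument effects, additive on the log
  scale (multiplicative on the raw scale). Two batches by default, one per
  study center. This is exactly the model the empirical-Bayes batch
  correction assumes, so correction quality is measurable.
* Detection dropout: independent Bernoulli per class with detection
  probabilities 0.9 (CRC, AA) and 0.85 (NAA, control) — mild
  class-dependent missingness. An optional missing-not-at-random mode
  (`censor_quantile`) additionally censors measurements whose latent
  abundance falls in the feature's lower tail; it is off by default.

What the generator does **not** emulate: real VOC chemistry and identity,
inter-compound correlation structure, retention-time drift beyond a
per-sample Gaussian jitter, storage/sampling artifacts, or covariate
confounding (age, sex, smoking). Tests passing on these cohorts show the
*pipeline machinery* is correct and honest (no leakage, correct
bookkeeping, recoverable signal recovered); they do not show that real
breath data carry comparable signal.

Chromatogram rendering (for the peak-picking path) places each feature as
a Gaussian RT peak (sd 2 s) in an assigned nominal-m/z channel with area
equal to its abundance, plus optional baseline drift and additive noise.
Determinism: identical `CohortSpec` + seed reproduce every output
bit-for-bit.

## Preprocessing

Noise removal is Savitzky–Golay (default window 9, order 3). Baseline
correction is asymmetric penalized least squares per m/z channel
(Whittaker smoother; default `lambda = 1e7`, asymmetry `p = 0.01`),
clipped at zero. Peak picking gates local maxima on SNR (default ≥ 5) and
width (≥ 1 s) and integrates trapezoidally between flanking minima; the
noise scale is estimated as the 84.1th percentile minus the median of the
channel, which stays valid after the lower half of the noise has been
clipped to zero. Alignment clusters peaks across samples by exact
nominal-m/z match and single-linkage RT chaining with tolerance 2 s
(typical TOF-GC resolution).

Missing means *not detected* (NaN), never zero, until scaling. The
prevalence filter keeps a feature if it is detected in **at least** 20 %
of at least one class (inclusive ≥, so exactly 20 % is kept). Total-
intensity normalization divides each sample's detected values by their
sum. Scaling imputes missing values as half the feature's minimum detected
value, log-transforms, centers, and applies Pareto (default) or
unit-variance scaling. Each stage is a plain function, so alternative
strategies can be substituted.

## Batch correction

The ComBat-style location/scale model is estimated feature-wise with class
indicators as protected covariates by default (the original study does not
state its design matrix; protecting class prevents the correction from
erasing biological signal, at the cost that correction is no longer blind
to labels — the label-permutation leakage test therefore runs without
covariates). Per-batch location (`gamma`) and scale (`delta^2`) estimates
are shrunk by parametric empirical Bayes (normal / inverse-gamma priors,
method-of-moments hyperparameters, iterated to 1e-4 relative change) or,
on request, by nonparametric posterior weighting. Surrogate-variable
analysis is the simple two-step form — residualize on the primary design,
SVD, keep components whose variance share beats the 95th percentile of
column-permuted residuals — and is off by default; the full iteratively
reweighted algorithm is out of scope.

## Model 1 — one-class CRC screen

With only 30 CRC cases, supervised marker selection is unreliable, so
screening is one-class: an Isolation Forest is trained on controls only
and CRC cases are scored as anomalies. The forest is implemented from
first principles (uniform subsample per tree, uniform split feature and
split point, depth cap `ceil(log2 n_sub)`); the anomaly score is
`s = 2^(−E[h]/c(n_sub))` with exact harmonic numbers in `c(n)` for
n ≤ 100 and the `ln + Euler–Mascheroni` expansion above. Each control is
scored leave-one-out (forest refit without it); cases are scored against a
forest on all controls. Defaults: 500 trees, `n_sub = min(256, n)` — the
algorithm's standard settings. The operating threshold fixes specificity
at 70 % on the pooled control scores, the study's recurring operating
point; whether its forest was trained on controls, cases, or everyone is
not stated, and "trained on controls" is this package's reading.

A caveat the synthetic cohorts expose: one-class screening is sensitive to
class-dependent detection rates. With controls detected slightly less
often than CRC, half-minimum imputation plants more extreme low values in
controls, which then look *more* anomalous than cases — the synthetic
Model 1 AUC falls below 0.5. This is a real failure mode of one-class
screening under differential missingness, reported as computed.

## Representative split

The study withholds an internal test set chosen by Isolation Forest but
does not define the rule. This package's rule: per class, fit an IF on the
class, exclude the top anomaly-score decile from test eligibility, then
draw the test samples stratified across anomaly-score quartiles of the
remainder. The test set is thus typical of each class and the construction
is reproducible; training keeps everything else, giving the study-scale
sizes (128 AA / 74 controls when withholding 10 per class; 123 AA when
withholding 15).

## Model 2 — marker panel

The base learner is a bagged random-forest classifier with sqrt-feature
subsetting (scikit-learn), wrapped with explicit per-tree bootstrap
membership. Importance is Breiman-style OOB permutation importance (per
tree: accuracy drop on its OOB samples when one feature's values are
permuted; averaged over trees), not impurity decrease — robust to scale
and faithful to an "internal iterative validation" reading. The iterative
procedure refits `n_iter` independent forests and averages; the full study-scale
budget is 1000 iterations × 1000 trees, and 100 × 100 is the desk-scale
default used by the bundled configuration, tests and acceptance script
(problem sizes chosen so a full run completes in about a minute).

Panel size: the study reports a 10-VOC panel but no selection rule. The
package's rule refits on top-k features over a k-grid and takes the
smallest k whose OOB Youden index is within one standard error of the
best; `force_k = 10` pins the study-style fixed 10-VOC panel. Panels are ordered
by |signed importance|, the sign taken from the difference of class means
(positive = higher in AA). Transfer to the CRC and CRC+AA contrasts refits
a forest restricted to the top-5 panel features, mirroring the study's use
of its 5 most predictive compounds.

OOB proximity between two samples is the fraction of trees, among those
where both are OOB, in which they share a terminal leaf (never-jointly-OOB
pairs get 0 with a warning; forests are sized so this is rare). PCoA uses
`d = sqrt(1 − proximity)`, which guarantees a Euclidean-embeddable
distance, double-centers `−½ J D² J`, and reports coordinates scaled by
square roots of the positive eigenvalues with variance fractions over
positive eigenvalues only. Evaluation sweeps all thresholds for ROC and PR
curves (trapezoidal AUCs) and anchors the operating point at the smallest
specificity ≥ the 70 % target, ties toward higher sensitivity. PPV from
rates on a finite sample rounds TP and TN to whole counts.

## Model 3 — hierarchical midlevel fusion

Submodel A discriminates AA vs (NAA ∪ control); submodel B discriminates
NAA vs control and never sees AA samples. Each submodel contributes its
samples' scores on the first principal coordinate of its OOB-proximity
PCoA (one coordinate per submodel, per the midlevel-fusion design; a
config flag allows more). Samples a submodel never saw are projected
out-of-sample: proximity to the training samples over *all* trees (OOB
proximity is undefined for unseen samples), then the classical PCoA
projection `−(v · (d² − r)) / (2√λ)` with `r` the training row means of
`D²`. All-trees proximities run slightly higher than OOB proximities, so
projected scores sit on a mildly compressed scale; the self-consistency
test bounds the median train-vs-projected gap at 10 % of the score range.

The final 3-class model is a random forest refit on the fused 3-column
score matrix (the staged-decision alternative reading of the hierarchy is
not implemented). Because the original study could not validate this model
independently, the package reports it on internal validation only (15
samples per class, representative-split selection) and labels the report
accordingly. Weighted accuracy is the mean of per-class recalls; 1/3 is
chance.

## Numerical choices and degenerate inputs

* Empirical-Bayes iteration: relative-change tolerance 1e-4, 500-iteration
  cap, warning + last iterate on non-convergence (same pattern for the
  baseline estimator).
* Zero-variance features: centered, not scaled, with a warning; ComBat
  refuses constant features (zero pooled variance).
* Isolation trees on constant data terminate as depth-0 leaves; the model
  stays valid and scores fall back to the subsample normalizer.
* PCoA with no positive eigenvalues returns a degenerate one-column
  embedding with a warning.
* All stage seeds derive from one master seed through `SeedSequence`, so a
  config + seed pair reproduces the full report byte-for-byte (timings
  excluded).

## Known limitations

* Feature-table synthetic cohorts draw features independently; correlated
  VOC blocks (shared metabolic origin) would stress panel selection in
  ways these tests do not measure.
* The desk-scale importance budget (100 × 100) has visibly wider
  importance dispersion than the study-scale budget; panel membership near
  the selection boundary can differ between budgets.
* Out-of-sample PCo projection mixes all-trees proximities with an
  OOB-proximity embedding; the scale mismatch is documented and bounded by
  test, not removed.
* The exclusion-cascade replay distributes flags over distinct synthetic
  patients; overlapping exclusion reasons (one patient, two flags) occur in
  real rosters and are supported by the cascade logic, but the default
  roster does not generate them.
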
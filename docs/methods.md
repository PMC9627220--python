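# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Pipeline overview

The unit of analysis is a *batch* (one preparation of a multi-herb
decoction, S1…S10). Inputs are per-batch LC-MS peak tables (peak id,
retention time in minutes, integrated area, ion mode) and bioassay
readouts. The pipeline is:

1. match peaks across batches into a common-peak matrix;
2. QC the matrix (internal-standard relative metrics, RSD/CV%, calibration
   linearity screen, fingerprint similarity);
3. turn raw assay readouts into oriented per-batch activities;
4. screen peaks by GRA, PLSR-VIP and BP-ANN/MIV per endpoint;
5. intersect the three selections (consensus) and report cross-endpoint
   overlaps.

## Common-peak matching

Peaks from all batches are pooled per ion mode, sorted by retention time
and clustered greedily: a peak starts a new cluster when it is more than
`rt_tolerance` (default 0.2 min, configurable) from the running cluster
median. A cluster becomes a common peak only if every batch contributes
exactly one member within tolerance of the consensus (median) RT; clusters
missing from any batch are reported and excluded; two same-batch peaks
inside the tolerance are an error rather than a silent merge. Peak identity
(P1…Pn) is assigned by ion-mode block (positive first) then consensus RT,
and is fixed at matrix construction so the three screens and the consensus
always speak about the same peaks. Pooled clustering makes the result
invariant to the order in which batch tables are supplied.

The legacy two-block TXT exchange layout (chromatogram RT/intensity block,
then an RT-sorted height/area block, single-byte encoding) is a documented
reconstruction of a dialect described only in prose; the reader reproduces
the writer's blocks losslessly and that round trip is the format's contract.

## QC statistics

* RRT and RPA are per-batch ratios to the internal-standard peak; by
  construction both are exactly 1 for the IS itself.
* RSD and CV share one formula, `100·sd/mean` with the sample (n−1)
  standard deviation — the population/sample choice is not standardized in
  this field, so it is fixed and documented here.
* The linearity screen regresses analyte/IS area ratio on relative
  concentration taken as 1/dilution (absolute component concentrations in a
  pooled QC sample are unknown), OLS per peak, and drops peaks with
  `R² < 0.99`.
* Fingerprint similarity is the uncentered cosine between each batch's
  common-peak area vector and the mean fingerprint across batches. The
  widely used similarity software for herbal fingerprints does not publish
  its algorithm; cosine against the mean reference is its documented
  default behaviour and is recorded in the report.

## Effect endpoints and orientation

Raw endpoints carry a `larger-raw-means-more-active` flag. Activities are
obtained by strictly monotone transforms that keep values positive (the GRA
mean normalization requires that): reciprocal for IC50-type endpoints,
`100 − x` for lower-is-better percentages (viability, healing),
`(max + min) − x` for lower-is-better counts, identity for FRAP. The
transform used is recorded per run. Orientation is the main gap this module
fills: screening literature asks for "positive correlation with activity"
without stating how decreasing-better endpoints were flipped.

Dose–response potency uses the four-parameter logistic on log
concentration (the log-inhibitor-vs-response variable-slope model of
standard dose–response software); the IC50 is the concentration at the
midpoint between the fitted floor and ceiling, which is exact for this
family at any Hill slope. Flat responses and non-convergent fits raise
errors carrying the residual norm rather than returning garbage.

## Grey relational analysis

Deng's coefficients with resolution `ρ = 0.5` and the min/max deltas taken
globally over all comparison sequences (the double min/max over sequences
and positions); a per-sequence variant exists but is not the default.
Sequences are mean-normalized first — raw areas span orders of magnitude
and the formula is scale-sensitive; `none` and `minmax` modes are
selectable. Selection uses the strict inequality `r > 0.8`. When every
delta is zero (all sequences identical after normalization) the coefficient
is defined as 1 by continuity.

## PLSR with VIP

NIPALS PLS1 on autoscaled data (centering, unit sample variance, ddof = 1).
The component count is chosen by leave-one-out cross-validation — with ten
batches, k-fold splits are unstable — as the smallest A whose
`Q² = 1 − PRESS/TSS` lies within 0.01 of the maximum over `A ≤ 5`, with
full per-fold refitting including the scaling. VIP is Wold's formula; the
implementation is verified against an independent SVD-based PLS1 and
against scikit-learn's `PLSRegression` predictions, and `Σ VIP² = p` is
asserted to 1e-8. Selection requires `VIP > 1` *and* a positive regression
coefficient (mirroring "positively correlated"); a sign-agnostic mode
exists for sensitivity analysis. Zero-variance predictors are dropped with
a warning.

## BP-ANN with MIV

A single-hidden-layer regressor (default `p–3–1`, logistic hidden units,
identity output) trained by L-BFGS on min-max-scaled inputs and output;
training is deterministic given the seed. With ten batches a single 8/2
train/test split is nearly degenerate, so the default is an ensemble of 20
seeded restarts (both the initialization and the split vary) whose MIVs are
averaged; fit reports carry R² on the train, held-out and whole sets. MIV
perturbations (`×1.1` / `×0.9`, `delta = 0.10`) are applied to the
*original-scale* data and rescaled inside the model, matching the
algorithm's definition, and are computed on all samples. For an exactly
linear predictor the construction gives `MIV_j = 2·delta·w_j·mean(x_j)`,
the closed form the tests pin down. The input width follows the
linearity-retained peak count rather than a fixed 70, and both are
supported.

## Consensus

Exact three-way set intersection per endpoint; relaxing any single method's
threshold can only grow the consensus (tested). The JSON report carries
each method's full score vector, all thresholds and seeds, and a content
hash, and serializes byte-identically for identical inputs, so threshold
sensitivity can be re-derived without recomputation.

## Synthetic benchmark

The generator's defaults emulate the ten-batch study design: 70 common
peaks split over two ion modes on a 2–48 min gradient, retention times on a
jittered grid (resolved peaks), log-normal areas with per-peak log-sd drawn
uniformly from (0.2, 0.65) (area CVs ≈ 20–70 %, within the 9–153 % RPA CV
range such fingerprints show), a mild multiplicative per-batch strength
factor (sd 0.05, mean 1) emulating orthogonal-design extraction variation,
and six endpoints whose raw values are mapped onto the reported assay
ranges (IC50 1.59–5.50 mg/mL, FRAP 143.83–873.83 µmol/L, viability
21.73–85.71 %, healing 21.50–44.46 %, migration 12–68.67, invasion
7.67–27) with 5 % relative assay noise.

Two structural choices matter and are deliberate:

* **The link acts on standardized abundances.** Each endpoint is a linear
  (or tanh-saturating) combination of the planted peaks'
  variance-standardized areas with coefficients drawn U(0.5, 1.5). On raw
  areas, a peak's influence would be dictated by its ionization response
  (areas span 1e4–1e6), making most planted peaks silent; standardization
  gives every planted peak a coefficient-controlled effect size.
* **Planted peaks co-vary.** The planted set of an endpoint shares a
  per-batch module factor (within-module correlation 0.85, implemented as a
  variance-preserving blend so each marginal stays log-normal). This
  emulates constituents co-released from the same source herbs under
  varying extraction conditions, and it is what makes individual active
  peaks trackable at n = 10: with eight mutually independent actives, each
  one's marginal correlation with the effect is ~1/√8 and no method can
  see it in ten samples.

With these defaults the three-method consensus recovers planted actives
with mean recall ≈ 0.85 and precision ≈ 0.6 over seeded replicates — the
residual false positives are the chance correlations an n = 10, p = 59
screen cannot exclude, which is a property of the design, not of the
implementation.

What passing these tests shows: the formulas, selection rules and their
interplay behave correctly on data with the study's shape, scales and
dispersion. What it does not show: performance on real fingerprints with
unknown correlation structure, retention-time drift beyond the jitter
model, missing or co-eluting peaks, or assay error that is not
multiplicative Gaussian. The generator makes no attempt to simulate raw
chromatograms or mass spectra; peak tables are the entry contract.

## Problem sizes and determinism

Oracle comparisons use 100 random 8×6 problems (PLS) and 1000 random
instances (GRA bounds); recovery is measured on 20 seeded datasets of
10×70. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical (spec, seed) pairs reproduce outputs
bit-for-bit, and the neural screen derives per-member seeds from the base
seed, so reports are reproducible end to end.

## Known limitations

* The published screening study deposits no raw data, so its
  data-dependent numbers (per-endpoint GRA counts, Q² values, consensus
  sizes) can only be reproduced in distribution on synthetic data; the
  printed consensus lists themselves are shipped as reference sets and all
  their cross-endpoint overlap statements are reproduced exactly by set
  algebra.
* The exact normalization and delta scope of the study's GRA, its SIMCA
  settings, and its ANN trainer are unstated; the defaults here are
  documented choices, all configurable.
* LOO Q² on ten batches is optimistic relative to 7-fold CV; values agree
  with k-fold only to the first decimal.
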
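# Methods

`dcepcr` implements an early-prediction pipeline for pathological complete
response (pCR) to neoadjuvant chemotherapy from breast DCE-MRI: low-level
convolutional features are extracted from tumor ROI patches at the
pre-treatment (T1) and early-treatment (T2) exams, a resampled rank-sum
stability procedure distills them into an Optimal Subset of Features
(OSF), and an SVM classifier is evaluated by leave-one-patient-out (LOO)
cross-validation and on an independent test cohort. Because the original
I-SPY1 TRIAL images cannot ship with the package, a synthetic-data module
generates phantom cohorts with known ground truth; every quantitative
claim made by the tests is therefore a claim about the *method*, not
about clinical data.

## Imaging model

A DCE series holds one pre-contrast and two post-contrast volumes
(acquired roughly 2.5 and 7.5 minutes after contrast injection). Two
semi-quantitative maps drive segmentation:

- peak enhancement `PE = (post1 - pre) / pre`,
- signal enhancement ratio `SER = (post1 - pre) / (post2 - pre)`.

Voxels with non-positive denominators are flagged invalid and never pass
thresholding. The tumor mask is the largest connected component of the
voxels inside a reader-supplied seed region with `PE > pe_threshold` and
`SER` within `ser_range`. The thresholds are configuration values
(defaults `pe_threshold = 0.7`, `ser_range = [0.9, inf)`); they are
deliberately documented as arbitrary defaults — tissue-calibrated values
belong to the data source, not to the method — and the phantom generator
is parameterized so that its tumors are recoverable at these defaults
(Dice >= 0.9 is asserted by the tests).

The classifier input patch covers the tumor and its immediate peritumoral
margin: a square of side equal to the clinical largest diameter (LD),
centred on the rounded tumor centroid in the slice with the largest
in-slice mask area, cropped from the *first* post-contrast volume and
bilinearly resized to 227 x 227. Unstated details are fixed as explicit
conventions: slice ties break to the lowest index, the centroid rounds
half-up, the crop window is half-open, out-of-bounds regions are
zero-padded, the LD-to-pixel conversion uses the in-plane spacing with a
minimum window of 8 px, and resizing uses bilinear interpolation with
edge clamping (which preserves the extremes of constant and ramp images
to interpolation accuracy).

## Feature extraction (pool2 contract)

Every extractor backend must map a 227 x 227 x 3 input to a
13 x 13 x 256 activation stack — the shape of the second pooling layer of
the classical AlexNet architecture — flattened to 43,264 values in
row-major spatial order with channel fastest:
`index = (row * 13 + col) * 256 + channel`. With both timepoints the T1
block occupies indices 0..43,263 and the T2 block 43,264..86,527
(86,528 per patient). `locate_feature` inverts the flattening so a
selected feature can be traced back to its activation map and cell — the
basis for visual inspection of what the selected features respond to.
Post-pooling activations are used rather than raw convolution maps
because pooling confers local translation tolerance.

Grayscale patches are min-max rescaled to [0, 1] and replicated to three
channels; a constant patch maps to zero so the zero patch is a fixed
point of the whole chain.

The default backend is a **deterministic filterbank**: two bias-free
conv+ReLU+max-pool stages (11 x 11 stride 4: 227 -> 55, pool to 27;
5 x 5 pad 2 to 256 channels, pool to 13) with seeded Gaussian filters.
Random convolutions are a standard untrained-feature baseline; the
backend needs no downloaded weights and is bit-for-bit reproducible.
A `"alexnet-pool2"` plug-in slot accepts a pretrained network, but note
that torchvision's AlexNet variant has a 192-channel pool2 and fails the
contract check by construction — the contract requires the original
(Caffe/MATLAB) 256-channel architecture. Any backend is probe-checked at
load.

## Stability feature selection

For ~100 patients and tens of thousands of features, single-shot
univariate filtering is unstable. The selection procedure layers three
set operations over a resampled filter:

1. per random 90% subsample of the training patients, keep features with
   a two-sided Wilcoxon–Mann–Whitney p strictly below `alpha = 0.001`;
2. per iteration, draw 10 such subsamples and take the **union** of their
   selections;
3. per held-out patient of a LOO loop, run 20 iterations and take their
   running **intersection** — features stable under resampling;
4. the **OSF** is the intersection of all per-patient sets — features
   stable no matter which patient is removed.

Defaults (20 iterations, 10 subsets, 90%, 0.001) are the procedure's
standard operating point and are echoed in every manifest. Subsamples
that lose a class are redrawn (and counted); an empty OSF is a legal,
logged outcome, not an exception.

The rank-sum test uses midranks, the exact null distribution for
tie-free columns when the combined n is at most 25 (the exact
distribution does not account for ties — the same convention as R's
`wilcox.test`), and a tie-corrected, continuity-corrected normal
approximation otherwise. The vectorized implementation is verified
elementwise against `scipy.stats.mannwhitneyu` and against a full
enumeration oracle in the tests.

Two implementation choices matter for reproducibility and speed:

- **Counter-based substreams.** Every draw comes from a stream keyed by
  `(seed, patient, iteration)`, so results are independent of evaluation
  order, any cell can be replayed in isolation, and the subset-draw
  digest in `SelectionResult` allows bit-exact replay.
- **Running-intersection restriction.** Iterations after the first
  compute p-values only on columns still in the running intersection.
  Because a column eliminated once can never re-enter an intersection,
  and draws do not depend on the restriction, the result is bit-identical
  to the unrestricted computation (asserted against an unrestricted
  reference in the tests) at a fraction of the cost. Once the running
  intersection is empty the remaining iterations are skipped.

### Null behaviour (known property)

The procedure does **not** control family-wise error under the null.
With 108 patients and 1,000 features of pure noise, roughly one feature
in three cohorts attains a full-cohort rank-sum p of 1e-4..4e-4 by
chance; such a feature stays below the 0.001 cut-off in essentially every
90% subsample and therefore survives all intersections. Empirically the
OSF is empty in about 60–70% of null cohorts, and when it is not, it
contains a single chance feature. The per-patient stable sets are empty
for >= 95% of patients whenever the cohort-level null holds. Permutation
checks (200k resamples) confirm the surviving features' p-values are
real, not artifacts of the normal approximation. Users who need a
stricter null should lower `alpha` or require a minimum OSF size.

## Classification and evaluation

The classifier is per-column z-scoring plus an SVM (linear kernel,
`C = 1`), a conventional choice when features outnumber patients; kernel
and regularization are configurable. The positive class is pCR and
decision scores are oriented so larger means more pCR-like. Scaling (and
clinical encoding/imputation) is fit on each training fold only.

- **LOO evaluation**: one score per held-out patient; the pooled scores
  form one ROC. Because the OSF is selected using *all* fine-tuning
  patients, fine-tuning LOO metrics are optimistically biased; every
  report carries this note, and the independent test is the unbiased
  surface.
- **Independent test**: a single model fit on all training patients.
- **AUC** equals the concordant-pair fraction with half credit for ties
  (Mann–Whitney identity; asserted against pair counting).
- **Operating threshold**: the maximizer of Youden's
  J = sensitivity + specificity − 1 over midpoints between adjacent
  distinct scores (plus sentinels beyond both extremes), with ties broken
  toward higher specificity and then the higher threshold; separable
  scores yield the gap midpoint. For the independent test the threshold
  comes from the test ROC by default, with a config switch for the
  training threshold — both are always reported.
- **Confusion metrics** are percentages at one decimal; prediction is
  positive when score >= threshold.
- **Subtype-stratified metrics** reuse the global threshold inside each
  molecular subtype; patients with missing subtype are excluded and
  counted, and a single-class stratum reports the undefined metric as
  not applicable.

Clinical variables (ER, PgR, HER2 0/1; molecular subtype as a single
3-level code) are appended after the image features when association
screening selects them: Mann–Whitney for age, Pearson chi-square without
continuity correction for categorical variables, significance at
p < 0.05, rows with missing values dropped per variable, and a warning
flag when any expected cell count falls below 5. Missing values in model
input are imputed to the training-fold mode and flagged.

## Synthetic data

- **Feature cohorts**: i.i.d. Gaussian columns; informative columns of
  the pCR class are mean-shifted by `effect_size * noise_sd`. The default
  cohort shape is the study composition (fine-tuning 30 pCR / 78 non-pCR,
  independent test 7 / 19; 10 informative of 1,000 features at effect 3).
  Gaussian mean shifts are the simplest model with controllable rank-sum
  power; the Monte-Carlo power of the 0.001 filter at effect 3 with
  40 + 40 patients is ~100% per informative column (measured over 200
  replicates).
- **Phantoms**: ellipsoidal tumors (additive Gaussian texture, tumor
  voxels multiplied by per-class post-contrast gains) in small volumes,
  default 8 x 48 x 48 voxels at 1 mm — deliberately desk-scale. The
  early-treatment (T2) series encodes the treatment effect: responders
  retain 60% of their excess enhancement and shrink to 70% radius,
  non-responders 90%/95%. The retention values keep treated responder
  tumors above the default PE threshold so the segmentation stage remains
  exercisable at both timepoints. Per-patient geometry jitter (center
  ±2 voxels, radius ±15%) comes from counter-based substreams so patient
  k is invariant to cohort size.
- **Clinical tables**: subtype-given-class interpolates between the
  pooled and the per-class subtype distributions of the study cohort
  (`assoc_strength` in [0, 1]); ER/PgR/HER2 are drawn conditional on
  subtype only (Luminal mostly ER+/PgR+; Triple Negative receptor-
  negative by definition, small flip probabilities keep every marker
  two-level), so the four markers inherit exactly the subtype's class
  association and become class-independent at strength 0. Age and race
  are always class-independent.

What the phantoms do **not** model: MR physics, coil/bias artifacts,
pharmacokinetics, irregular tumor shapes, multi-site variation. Passing
tests therefore demonstrate the correctness and calibration of the
pipeline's computations, not clinical performance; the headline numbers
published for the real I-SPY1 cohorts require the original images and
pretrained network weights and are out of scope here.

## Pipeline and problem sizes

The staged pipeline (simulate → segment → roi → extract → select →
evaluate → report) hands plain files (npz/CSV/JSON) between stages and
writes a manifest per stage (config echo, seed, input hashes, library
versions); timings go to a separate log so primary outputs are
deterministic. The default desk-scale run uses the full study shape
(108 + 26 patients, both timepoints) with 1,000 features subsampled
seeded from the 86,528 filterbank features — selection cost scales with
the feature count and 1,000 columns preserve every statistical property
being exercised. The whole run takes a few minutes on one CPU; test and
acceptance workloads use the same sizes or smaller.
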
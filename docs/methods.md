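# Methods

## The classification problem

Infrared breast thermography images the skin-surface temperature field;
a tumour's elevated metabolism raises the local temperature, so a lesion
shows up as a hotspot. A screening study contributes five views per
patient — front, left 45°, left 90°, right 90°, right 45° — as thermal
matrices: grids of per-pixel temperatures in °C. Alongside the images,
a clinical questionnaire records mostly discrete answers (complaints,
symptoms, signs, menopause, family history, previous exams, lifestyle)
plus two continuous features (age at screening, menarche age).

The pipeline classifies a patient as healthy or sick by **late fusion**:

1. One small CNN per view maps a square, single-channel image to a
   probability pair (P(healthy), P(sick)) via a softmax head. Each view
   model is trained independently.
2. The per-view pairs are concatenated in a fixed order (front, right 45°,
   left 45°, right 90°, left 90°) into a fusion tuple — 10 elements for
   five views, 6 for the default three-view setup.
3. A small MLP on the encoded clinical features emits a sigmoid score in
   [0, 1]; thresholding at 0.5 gives the *clinical-data decision*
   (score < 0.5 → healthy, otherwise sick; the boundary case classifies
   sick, since only strict inequalities are conventionally defined and a
   screening context prefers the sensitive tie-break).
4. The decision (or optionally the raw score, `clinical_mode="probability"`)
   is appended as the final fusion element (11 for five views, 7 for three).
5. A final MLP ("fusion network") is trained on the tuples produced by the
   frozen components. Its argmax is the diagnosis; its P(sick) drives the
   ROC and precision–recall curves.

Training is strictly two-stage: component weights are bit-frozen during
fusion training (verified by a test). Joint fine-tuning is deliberately
not implemented.

## Architectures

Two reference conv stacks are provided. Each block is a 3×3 convolution
with stride 2 and padding 1, ReLU, then 2×2 max pooling, so one block
shrinks the spatial side by ~4×.

- **Model 1**: channels 32/64/128 for every view (640 px input → 10 px
  feature map → hidden dense layer → 2-unit softmax).
- **Model 2**: channels 45/90/135/180 for the lateral views and
  50/100/150/200 for the front view.

The sources specify channel counts, stride and pool size only; kernel
size 3, padding 1, ReLU, a single 64-unit hidden dense layer, softmax
output, and the 32-unit clinical MLP / 16-unit fusion MLP are
conventional completions and are all configurable. A spec whose spatial
trace collapses to zero (e.g. Model 2's four blocks on a 64 px test-scale
image: 64 → 16 → 4 → 1 → 0) is rejected with the offending depth; the
pipeline's `auto_depth` option instead trims trailing blocks and logs the
adjustment.

The networks are implemented in a compact numpy engine (`thermofusion.nn`)
with explicit backpropagation (verified against central finite
differences to ~1e-9 relative error), seeded He initialisation, and
SGD (default, learning rate 0.001) or Adam optimisers. Adam is
non-default: on cohorts of a few hundred patients it overfits quickly.
Loss is 2-way cross-entropy for the CNNs and fusion net, binary
cross-entropy for the clinical net. Training is batch-wise (default batch
8, reshuffled each epoch from the run seed) and stops early when the best
epoch loss fails to improve by more than 1e-4 for 5 consecutive epochs —
an operationalisation of "stop before the loss flattens". Everything is
deterministic given the seed: identical seed + data reproduce identical
weights and loss histories bit-for-bit.

## Preprocessing

**Image QC.** A study is kept only if every required view is present and
free of disqualifying defects. A blurry or missing static view with a
clean dynamic-protocol counterpart is substituted (recorded in the QC
report) rather than removed. Removal reasons: `missing_views`, `blurry`,
`injury`, `protocol_violation`. The filter is idempotent.

**Resizing.** Thermal matrices (natively 640×480) are stretched to a
square by bilinear interpolation with corner-aligned sampling — a direct
transform, not padding, so the vertical axis is stretched. Corner
alignment makes small cases exactly hand-checkable; outputs are convex
combinations of inputs, so the temperature range never expands.

**Clinical cleaning.** Ages outside [1, 119] years (both bounds
configurable; the defaults exclude the recorded 0- and 120-year
anomalies) remove the patient; blank discrete answers become the literal
category `"not answered"`; missing menarche age is imputed with the
median (fit on the training partition and passed in for leakage-free
test-set cleaning).

**Encoding.** Discrete features are one-hot encoded over the categories
observed in training (unseen test categories map to an all-zero block);
continuous features are min–max scaled with training-fitted bounds. A
constant training column maps to 0. Test values may fall outside [0, 1];
they are neither clipped nor refitted, and a test asserts the scaler
parameters are unchanged after seeing test data.

**Split.** Stratified 80/20 with the test count rounded half-up — the
only rule consistent with both published class rows (157 → 126/31,
84 → 67/17). Patient assignment is a seeded within-class permutation.

## Evaluation

Sick is the positive class. From the confusion counts: accuracy
(TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), F1 the harmonic mean of precision and sensitivity. A zero
denominator yields NaN with a warning — never a silent 0. ROC and PR
curves are computed via scikit-learn's threshold sweeps; both AUCs use
trapezoidal integration (PR over the recall axis, keeping the best
precision per distinct recall; average precision is available as an
alternative). The ROC AUC equals Mann–Whitney concordance with half
credit for ties — tested against a brute-force pairwise oracle. The PR
no-skill baseline is the positive prevalence. Reports carry a cohort
fingerprint so with/without-clinical comparisons refuse mismatched test
sets; percent output is rounded to one decimal to match the published
table style.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not breast anatomy or bioheat physics.

- **Baseline field**: 2–4 broad 2-D Gaussian bumps mirrored about the
  vertical midline (bilateral symmetry), amplitudes 0.4–1.2 °C, over a
  per-patient mean of 33 ± 0.5 °C, plus i.i.d. pixel noise (default
  0.3 °C). The bump parameters are drawn once per patient and shared by
  all five views, since the views image the same torso.
- **Lesion**: sick patients carry one Gaussian hotspot (default peak
  elevation ΔT = 2 °C, σ = min(H, W)/8 px). It appears in the front view
  and the two ipsilateral views, absent contralaterally — fusion can only
  help if the views carry correlated signal. The hotspot is anchored near
  the warmest point of the affected side (lesions favour
  well-vascularised regions), with its amplitude referenced to the field
  maximum, so the cohort's max-temperature contrast tracks ΔT directly
  and increases monotonically with it.
- **Clinical records**: seven informative binary features (complaints,
  symptoms, signs, nipple changes, wart signs, family history, cancer in
  family) have "yes" rate 0.15 for healthy and 0.15 + `clinical_effect`
  for sick; body temperature class shifts similarly; age is
  N(50, 12²) years for healthy, shifted by 20 × `clinical_effect` years
  for sick; twelve lifestyle/history binaries and three multi-category
  features are class-independent. `clinical_effect = 0` makes the classes
  identically distributed. The default effect 0.3 is a moderate
  association; "strong" experiments use 0.75, i.e. a ~0.9 vs 0.15 symptom
  rate.
- **Defects**: blur (Gaussian smoothing escalated until gradient energy
  halves), missing view, injury artefact, protocol violation, age 0,
  age 120, blank questionnaire fields — each injected after clean
  generation with configurable per-patient rates, recorded in
  `qc_flags`/`defect_views` so QC behaviour is exactly testable. With
  probability `dynamic_backup_rate` (default 0.3) an affected view has a
  clean dynamic-protocol counterpart available for substitution.

No quantitative lesion contrast is published for this modality; the 2 °C
default is a simulation parameter chosen as a clearly-visible but not
trivial elevation relative to 0.3 °C pixel noise and ~1 °C baseline
relief. What passing tests show is that the *pipeline mechanics* recover
a planted multi-view + tabular signal and report honest chance-level
accuracy when no signal exists; they do not certify performance on real
thermograms, whose anatomy, acquisition artefacts and feature
correlations the generator does not model.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced scale, chosen as the
smallest sizes at which the mechanisms are statistically visible:
64×64 px images (640-px full scale remains available), 200-patient
cohorts for effect-recovery experiments (40–80 for null checks), view
models trained ≤ 20 epochs, tabular nets ≤ 200–300 epochs. The null
check asserts pooled accuracy within 3.3 binomial standard deviations of
0.5; effect-ordering checks average over five seeded replicates. Min–max
image normalisation is per image; degenerate (constant) images scale to
zero. Ties in max pooling split gradient equally; softmax is
max-stabilised; probabilities are clamped by ε = 1e-12 inside logs.

## Known limitations

- No bioheat modelling, anatomy, or dynamic-protocol cooling series
  (protocol is metadata only); real-mode QC trusts curator-provided
  defect flags rather than detecting blur/injury from pixels.
- Published cohort-specific accuracies are not reproduction targets: they
  depend on the external screening cohort and unspecified per-view epoch
  counts. The package reproduces the formulas, the procedure, and the
  qualitative orderings (fusion ≥ best single view; adding the clinical
  decision does not hurt and typically helps).
- The published test-set counts (31 healthy / 17 sick) are arithmetically
  inconsistent with some published percentages (e.g. sensitivities that
  are not multiples of 1/17); the split follows the published counts and
  the evaluation module reproduces formulas, not those specific values.
- No data augmentation, cross-validation, pretrained backbones, or
  hyperparameter search; class imbalance is left unweighted, matching the
  original procedure.
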
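# Methods

This note records the models, parameter choices and numerical conventions
behind `dsaflow`, and what the synthetic phantoms do and do not establish
about behaviour on clinical data.

## Phase model and temporal features

The analysis treats a DSA run as a sequence of per-frame structure
presences over five classes: carotid artery, circle of Willis, vein,
venous vessel, venous sinus. A class is *present* on a frame when some
detection of that class has confidence ≥ τ; ground-truth annotation rows
(no score) always count. τ defaults to 0.5, the conventional detector
operating point — true-structure confidences from a well-trained detector
sit well above it, so the exact value is not critical; it is configurable
everywhere.

Phase labels are assigned per frame in this precedence order: venous
content (sinus present → late venous, otherwise early venous) over
arterial content over emptiness. Venous-over-arterial precedence is
deliberate: the venous phases are defined by their venous content, and
arteriovenous shunting *is* arterial–venous co-occurrence. Empty frames
before the first detection are pre-contrast, after the last are
post-contrast, and strictly between the last arterial and first venous
presence are capillary. The early/late arterial split uses the frame of
maximal summed detection-box area among pure-arterial frames as the start
of the late phase (ties: earliest maximal frame): box area is a monotone
proxy for completeness of the filling vascular tree. Interior empty frames
not in the arterial→venous gap (impossible under contiguous schedules, but
possible with a flaky detector) inherit the previous frame's label — a
documented degenerate-case policy rather than an error.

The five binary features compare first/last presence frames.
"Before the end / before the disappearance" is read inclusively
(co-occurrence on the washout frame still counts), hence `≤` in T1, T2 and
T4; "appears before venous vessels" is a strict `<` in T3. A missing
left-hand event yields 0; in T3 a present sinus with venous vessels never
seen yields 1. T5 is 1 iff no frame is labelled capillary. Because the
features are min/max reductions over *all* frames, single-frame detector
mistakes in the middle of a structure's interval cannot change them; only
errors at interval endpoints can, and then only by one frame.

Key frames for radiomics are `f_i = first + round(i·span/4)`, i = 0..4,
round-half-up, over the developed span (first to last frame with any
detection). Short spans repeat indices. An alternative phase-snapped
sampler (middle frame of each named phase, falling back to the
equal-proportion frame) is exposed but not the default, since
equal-proportion sampling is the simpler, assumption-free rule.

## Radiomics bank

All features are computed on the whole frame — the method uses no lesion
segmentation, so no ROI mask exists. Per frame:

* **16 intensity features** of the raw gray values: mean, median, min,
  max, range, variance, SD, skewness, kurtosis (Pearson, non-excess),
  energy, RMS, entropy (256-bin histogram over the frame's own range,
  log₂, 0·log 0 = 0), uniformity, mean absolute deviation, 10th and 90th
  percentiles. On zero-variance frames skewness and kurtosis are defined
  as 0.
* **54 texture features** on the 32-level equal-width quantized frame:
  22 gray-level co-occurrence statistics (distance 1, four directions
  0°/45°/90°/135°, matrices symmetrized, normalized and averaged over
  directions before statistics), 16 run-length statistics (statistics per
  direction, then averaged) and 16 size-zone statistics (zones are
  8-connected). Degenerate values on constant images are fixed per
  feature: correlation and both information measures of correlation are
  0 (their normalizers vanish); the homogeneity-type features are 1.
* **280 wavelet features**: a two-level Haar decomposition with symmetric
  padding, *keeping both approximation images*, yields exactly 8 subbands
  (LL1, LH1, HL1, HH1, LL2, LH2, HL2, HH2). One plain level yields 4
  subbands and a plain two-level pyramid 7; retaining LL1 is the minimal
  convention that produces 8. Per subband, 35 features: the 16 intensity
  features plus the first 19 of the canonical 22 co-occurrence features
  (through inverse variance; the three dropped are maximum probability,
  sum entropy and sum of squares). The per-subband composition is a
  package convention — only the counts 16/54/8/280/350/1,750 are fixed by
  the method — and is configurable.

Quantization level (32), co-occurrence distance (1) and wavelet (Haar)
follow common 2D radiomics practice and are arguments, not constants.

## Detection evaluation

Boxes are 0-based half-open pixel rectangles, so areas and IoU are exact
integer arithmetic. AP is the all-point interpolated area under the
precision–recall curve (precision envelope `p(r) = max precision at
recall ≥ r`), the modern convention for region-proposal detectors;
matching is greedy in descending score (ties by stable input order), one
truth per prediction, at IoU ≥ 0.5. Classes with zero ground truth are
excluded from mAP — their recall is undefined — and reported separately.

The reference detector is a deliberately simple instrument for phantoms:
per-pixel maximum over the stack as background estimate, contrast depth
thresholded at 45 gray levels, 8-connected components of ≥ 9 px become
boxes, class = nearest canonical layout anchor, score = mean contrast
depth / full rendering depth. Components nearest the nidus anchor are
discarded (the nidus is not one of the five reportable classes). It makes
no claim outside the canonical phantom layout.

## Phantom generator

The generator's purpose is exact, schedule-derivable ground truth, not
visual realism: no vessel trees, X-ray physics or patient motion. Videos
are 20–50 frames at 166–333 ms/frame, matching clinical acquisition
rates. Structures are flat templates at a fixed anteroposterior layout
(artery inferior-center, Willis ring central, veins superior, sinus
superior-lateral), rendered as intensity dips of up to 120 gray levels
below a background of 200, with 2-frame linear ramps at onset and offset
(so confidence thresholding sees genuine half-contrast frames) and
additive Gaussian noise, default SD 8 — a contrast-to-noise ratio at
which a thresholding detector is reliable but not trivially so.

Schedules draw onsets/offsets with uniform jitter inside windows that
preserve the diagnosis orderings: normal runs place all venous onsets
after arterial washout with a 1–3 frame capillary gap and venous order
vein → venous vessel → sinus; AVM runs place the sinus onset 2–4 frames
after the artery onset (before arterial washout), veins before Willis
washout, sinus before venous vessels, and no gap. No quantitative
clinical phase timings are published for this setting; the windows are
package choices constrained only by the orderings, with cross-class
margins of ≥ 2 frames so that single-frame detection jitter cannot flip
ground truth. The grade surrogate couples the two things clinical grading
tracks in images — lesion size and shunt severity: high-grade cases get a
15–18 px nidus and a 2-frame-earlier sinus onset versus 9–12 px for low
grade, with no claim of clinical fidelity. Cohort class counts use
round-half-up; 305 cases at AVM fraction 152/305 give exactly 152/153.

What phantom results do establish: the correctness of the temporal logic,
the evaluation machinery, and the leakage discipline of the protocol.
What they do not: clinical detection difficulty (real vessels are not
disjoint templates), realistic radiomics effect sizes (phantom group
differences are strong, so AUCs near 1 are expected by construction), or
the clinical headline metrics, which require the private cohort and a
trained detection network.

## Selection and classification

ISR realizes sparse representation of the label vector as L1-penalized
least squares `argmin ‖y − Xw‖² + λ‖w‖₁` (labels −1/+1, features
standardized on the given table, zero-variance columns dropped with score
0), solved by coordinate descent; K subsample iterations (default 100,
class-stratified fraction ρ = 0.8 without replacement) are averaged into
`score_j = mean_k |w_kj|`. K, ρ and λ are not fixed by the method; they
are configurable and logged. λ may be numeric, `"auto"` (5-fold
cross-validated, chosen once per table) or `"max_frac:f"` (fraction of the
all-zero penalty λ_max — the modelling pipeline's default at f = 0.1,
cheap and deterministic, re-resolved inside every training fold).
Solver tolerance is near machine precision for narrow problems (p ≤ 50,
where tests compare objectives against a brute-force implementation) and
1e−3 for wide ranking problems, where it does not affect which
coefficients are large.

The classifier is a linear SVM (p ≫ n after radiomics extraction favors
linear; RBF available by config) with C chosen from {0.01, 0.1, 1, 10} by
inner stratified CV on the training fold. Scores are SVM decision-function
values and predicted labels their sign; a Platt-calibrated probability
threshold would add an inner CV without changing any ranking-based
metric. Evaluation protocols: leave-one-out with standardization, ISR
selection and the SVM fit all re-run on the n−1 training cases of every
fold (the leakage-free protocol; selecting once on the whole cohort is
available behind the explicit `selection_scope="cohort"` option, offered
only for sensitivity analysis because it is optimistically biased — the
leakage-canary test shows the size of that bias), and a stratified 7:3
split with LOO
model selection on the 70 % cohort and a single evaluation on the
untouched 30 %. AUC is the Mann–Whitney statistic (ties ½); its 95 % CI
is a stratified percentile bootstrap, 2,000 resamples by default.
Grading uses the identical machinery on AVM cases only (positives = high
grade) under the cross-validation protocol.

## Problem sizes and determinism

Reported phantom experiments use 96×96 frames, 50-seed recovery suites,
a 120-case diagnosis cohort and a 100-case grading cohort — sizes at
which every quantity in `scripts/acceptance.py` recomputes from scratch
in a few minutes while leaving class counts large enough for stable LOO
estimates. Every random draw flows from an explicit seed through
`numpy.random.default_rng`; renders, feature vectors and CSV writers are
bit-deterministic, and all evaluation results are reproducible from the
logged seed and config.

## Known limitations

* The phantom's radiomics signal is stronger than clinical reality;
  phantom AUCs validate the protocol, not clinical performance.
* The reference detector is layout-bound; clinical use requires an
  external detector emitting the detection-table format.
* The 35-feature per-subband wavelet composition is a convention; only
  the counts are fixed by the method.
* Grading is binary (high/low); the full five-level severity scale and
  calibration analysis are out of scope.
* DICOM support is read-only (multi-frame XA); no de-identification.
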
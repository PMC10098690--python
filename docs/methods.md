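# Methods

This note documents the models, numerical choices and limitations of
`thermaffect`. It is written for users who need to judge what the package's
validation results do — and do not — say about real thermal-imaging data.

## 1. Problem setting

Spontaneous emotions produce small (tenths of a degree) changes in facial
skin temperature with a regional structure: cheek warming in sadness and
disgust, nose-tip cooling in the same states, forehead cooling under fear
and sadness and warming under anger. An analysis contrasts two frames per
subject — *onset* (start of the emotional episode, the within-subject
baseline) and *apex* (peak intensity) — so that each subject is their own
thermal control. Eyeglasses (opaque to long-wave IR) and facial hair make
parts of the face uninformative, which motivates the three region schemes:
six main regions excluding the eyes (`main6`), their 27-tile decomposition
(`sub27`), and the 11 tiles chosen to avoid every occluder (`sel11`).

## 2. Synthetic data generator

The real spontaneous-emotion database with onset/apex thermal frames is
access-restricted, so the package ships a generator that emulates its
structure and provides exact ground truth.

**Face model.** A warm superellipse (|x/a|^n + |y/b|^n ≤ 1, default
exponent n = 8) on a cool background; default image 160×128 px, face
semi-axes 72×54 px. The high exponent keeps all fractional ROI rectangles
inside the silhouette; the analytic area `4ab·Γ(1+1/n)²/Γ(1+2/n)` is the
oracle for segmentation-area tests. Baselines (°C): background 25, face
34, forehead 35.5, nose tip 33.5, cheeks 35, mouth 35.25, chin 34.5, eye
band 36 — a plausible ordering (periorbital warmest, nose tip coolest),
with values chosen as exact binary fractions so identity cases are
bit-exact.

**Emotion signatures.** Per-class apex temperature deltas (°C):

| emotion  | forehead | nose tip | cheeks | mouth |
|----------|---------:|---------:|-------:|------:|
| happy    |          |          |  +0.3  | +0.3  |
| disgust  |          |   −0.4   |  +0.4  |       |
| fear     |  −0.3    |          |        |       |
| surprise |  +0.2    |          |        | +0.2  |
| anger    |  +0.4    |          |        |       |
| sad      |  −0.3    |   −0.4   |  +0.4  |       |

The sign pattern follows the physiology literature; the magnitudes are
**synthetic free parameters**, not physiological measurements — the source
studies report directions, not portable effect sizes. Between-subject
variation is modeled as Gaussian jitter on each delta (default SD 0.1 °C),
sensor noise as i.i.d. Gaussian per pixel (default SD 0.05 °C), and
subjects get a Gaussian baseline offset (SD 0.2 °C).

**Cohort.** Default class sizes mirror the screened real cohort — happy 99,
disgust 81, fear 55, surprise 65, anger 56, sad 73 = 429 pairs. Head motion
between frames is a similarity transform applied to the apex frame only
(the onset frame is the reference): rotation U(−2°, 2°), scale U(0.98,
1.02), shift U(−3, 3) px — small spontaneous head movements.

**Occlusion.** Eyeglasses render the eye band near ambient (26 °C); beard
(lower cheek tiles + chin + the band between mouth and chin), mustache (the
upper mouth row) and bangs (the upper two forehead rows) render at a hair
temperature of 31 °C. Occluder temperatures fluctuate between frames
(SD 0.5 °C, drawn independently for onset and apex): hair and spectacle
emission varies with posture, airflow and reflections. This fluctuation is
what makes occluded pixels *harmful* rather than merely constant — a
constant occluder would cancel exactly in the apex−onset difference.
Occluder masks are built from the same grid-edge arithmetic as the ROI
layout, so the guarantee that no occluder touches a `sel11` tile holds
pixel-exactly for any face size. Images are written as 8-bit grayscale PNG
with a linear calibration record (default 20–40 °C, quantization step
≈ 0.078 °C).

**What the generator does not model:** spatial temperature gradients within
regions, vascular texture, perspiration, breathing artifacts, non-rigid
expression deformation, camera fixed-pattern noise, drift, or partial/soft
occluder boundaries. Passing tests therefore demonstrate that the *pipeline
mechanics* are correct and that the occlusion-avoidance logic works under
the stated noise model — they do not certify accuracy levels on real
thermal data, where effect sizes and artifacts are far less favorable.

## 3. Preprocessing

**Calibration.** `T = T_min + g/g_max · (T_max − T_min)` — strictly
monotone, exactly invertible at grid points. All nine features are
affine-consistent in temperature, so results do not depend on the absolute
calibration, only on its linearity.

**Face extraction.** Median filter (5×5) → Gaussian smoothing (σ = 2) →
Otsu threshold → largest connected component. Otsu operates on relative
contrast, making the step invariant to adding a constant temperature.
Parameters are config-exposed; the originally described filter sizes are
not published.

**Registration.** A 4-parameter similarity transform (rotation, log-scale,
2-D shift, anchored at the image center) estimated by least squares on
Gaussian-smoothed intensities: initialization from the two face masks
(centroid shift, √area-ratio scale), Powell optimization at half
resolution, then a short full-resolution polish. Parameters are bounded to
a plausible head-motion range (|rot| ≤ 15°, scale 0.85–1.18, |shift| ≤ 25
px); unbounded search can drift onto the degenerate no-overlap plateau
where the objective is flat. The acceptance residual is the **median**
absolute temperature difference over the apex face mask (threshold 0.5 °C):
a robust statistic, because bilinear interpolation across sharp internal
edges (eyeglass rims, hair lines) produces large pointwise errors even
under perfect alignment. Direction: onset is resampled into apex
coordinates, since ROI boxes are drawn on the apex frame and copied to the
onset frame. Measured recovery error over a ±10°/±5%/±8 px grid is ~0.05°,
~0.0004 scale, ~0.04 px median — far inside the (0.5°, 0.01, 1 px)
tolerances asserted in tests.

## 4. ROI layout

Region rectangles are fractions of the face bounding box (the original
regions were drawn by hand and are not recoverable; the fractional layout
is digitized qualitatively and fully overridable via config). Forehead =
upper band split 3 rows × 4 cols (R1–R12, row-major; R9–R12 is the bottom
row), nose tip = central 12% square (R13), each cheek a 3-row strip
(R14–R16 left, R17–R19 right, top first), mouth a 3-row × 2-col grid
(R20–R21 above the lips — the mustache band — R22–R23 upper lip, R24–R25
lower lip), chin 1×2 (R26–R27). `sel11` = {R9–R13, R14, R17, R22–R25}:
lower forehead row, nose tip, upper cheeks, lips. Pixel mapping uses
monotone half-up rounding of shared grid edges, so sibling tiles partition
their parent exactly (no gap, no overlap) at any resolution; sub-ROI
windows that collapse below 2×2 px raise an error. The difference is
defined as `Xd = apex − onset` (warming at apex is positive).

## 5. Features and outlier filter

Nine statistics per region (see README). Variances are population
variances (divide by l·m), matching the 1/(l·m) normalization of the mean;
a `sample_variance` flag switches to ddof = 1. Medians of even-sized
samples average the two central order statistics. The class-wise outlier
filter computes per-class, per-column mean and SD and drops a row when
*any* of its features falls outside ±3 SD of its class; zero-SD columns are
skipped. Note the multiplicity consequence: under independence the
expected removal fraction is ≈ 1 − 0.9973^p, i.e. ~2% at p = 9 but ~48% at
p = 243 — the filter is intentionally faithful to the stated rule rather
than corrected, and the removal log is returned so users can audit it.

## 6. Feature ranking

* **ANOVA** — per-feature one-way F (scale-free), descending.
* **PCA** — columns standardized; components retained to 95% explained
  variance; each feature scored by its maximum absolute *loading*
  (component weight × component SD, i.e. the feature–component
  correlation). Plain component weights would tie all independent features
  near 1; the variance-weighted loading expresses "importance to the
  dominant structure". PCA ranks original features so that downstream
  column counts refer to features; a component-projection mode
  (`pca_project`) is available.
* **NCA** — diagonal-weighted neighborhood components analysis: maximize
  the expected leave-one-out soft-neighbor accuracy
  `Σᵢ Σ_{j≠i, yⱼ=yᵢ} p_ij`, `p_ij ∝ exp(−Σ_k w_k²(x_ik−x_jk)²)`, minus an
  L2 penalty λ‖w‖² (λ = 1/n), by L-BFGS-B with the analytic gradient on
  standardized features; rank by |w|. Distances are used raw (not
  rescaled): shrinking them flattens the softmax and buries the signal
  gradient under the regularizer. The row-wise softmax is stabilized by
  subtracting each row's minimum distance. `seed` perturbs the all-ones
  initial weights by 1%; non-convergence within `max_iter` is flagged on
  the result, never raised.
* **NB** — each feature scored by its single-feature Gaussian naive-Bayes
  accuracy under stratified 5-fold CV (variance floored at 1e−9). The
  scorer is vectorized across features and cross-checked against
  scikit-learn's `GaussianNB` in the tests.

Selection depth defaults: 50 for PCA/ANOVA, 10 for NCA/NB. Rankers are fit
**inside each training fold** (no selection leakage); a `global_selection`
flag fits selection once on the full task data to mimic protocols that
select before cross-validation. The validation suite uses the
fold-internal mode.

## 7. Classification and evaluation

15 one-vs-one tasks for 6 classes; the majority class of each pair is
randomly downsampled (seeded) to the minority size; stratified 10-fold CV;
features z-scored with training-fold statistics. SVM: RBF kernel, C = 1,
γ = 'scale', stopping tolerance 0.001 ("epsilon" in some toolkits' naming —
RBF-SVC has no kernel epsilon parameter). MLP: stochastic
backpropagation, learning rate 0.01, momentum 0.2 (sometimes called the
backpropagation rate), 500 epochs, 6 hidden layers of width 32 (an
alternative reading — one 6-unit layer — is available via
`ClassifierSpec(narrow=True)`).

Per-class accuracy is the arithmetic mean of the class's five pairwise-task
accuracies, and the overall accuracy the mean of the six class means —
mirroring the table structure in which each class has one number per
selector/classifier. Pairwise majority voting (`pairwise_vote`) is provided
for true multiclass prediction but is not what the report aggregates.
Cohen's κ uses the standard `(p_o − p_e)/(1 − p_e)` on the task confusion
counts; on balanced tasks, accuracy a implies κ ≈ 2a − 1, so ~95% accurate
models yield κ ≈ 0.90. Evaluations in this literature sometimes report
κ ≈ 0.67 alongside ~95% accuracies, a pairing that is internally
inconsistent under this definition; the package implements the standard
statistic rather than reverse-engineering such numbers.

## 8. Study conditions used by the validation suite

Problem sizes were chosen so the whole suite runs comfortably on a single
CPU: the null calibration uses one 600-subject cohort (100 per class,
identity motion, so onset frames need no resampling) with 20 label
permutations, ANOVA + SVM; the registration criterion uses a 27-point
motion grid; signal recovery runs the full pipeline (registration included)
on the default 429-pair cohort, clean and fully occluded, with NCA and NB
selection and the SVM classifier — the headline selector/classifier
combinations. Measured outcomes at these conditions: null accuracy ≈ 49%
and κ ≈ −0.02 (chance); every clean model/selector cell ≥ 0.91; under
full occlusion `sel11` stays ≥ 0.96 and beats `main6` on the NB selector by
2–3 points. The occlusion margin is modest because `main6` retains two
fully unoccluded signal carriers (nose tip; the un-occluded thirds of the
cheeks), which is itself consistent with the motivation for sub-region
analysis.

## 9. Known limitations

* The fractional ROI geometry is a reconstruction, not the original manual
  boxes; absolute accuracies depend on it only weakly (features are
  region-aggregate statistics), but tile-level feature identities do.
* Registration assumes a global similarity transform; non-rigid expression
  deformation is not modeled (and is absent from the generator).
* The NCA objective is non-convex; different seeds can reorder features
  with near-tied weights. Rankings of the planted-signal kind used in the
  tests are stable.
* With 243 features the 3-SD any-feature outlier rule removes a third or
  more of instances (multiplicity, §5); this matches the stated rule but
  users may prefer a per-feature Bonferroni-style threshold on real data.
* Synthetic accuracies should not be read as predictions of real-data
  performance (§2).
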
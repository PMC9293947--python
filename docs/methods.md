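# Methods

## The construct

Hypomimia reduces the amplitude and frequency of both spontaneous facial
expressions and voluntary (speech-related) facial movement.  During a
freely spoken monologue the lower face moves mostly with speech and the
upper face mostly with spontaneous expression, so variability of facial
geometry and of skin texture over one recording carries the signal.
Every marker in this package is therefore the **sample standard
deviation (n−1 denominator)** of a per-frame scalar; a perfectly still
face yields exactly zero for all of them, and all twelve are expected to
decrease as hypomimia worsens.

Two families of per-frame scalars are used:

* **Geometric** — Euclidean distances between landmarks divided by that
  frame's inner-eye-corner distance (IED, landmarks 39–42), angles in
  degrees (unsigned, in [0°, 180°]), and the eye-contour shoelace area
  divided by IED².  Per-frame IED normalisation cancels face scale and
  camera distance; the IED² normalisation of the aperture area is this
  package's choice (an un-normalised area would break scale invariance
  that every other marker has).  The eyebrow line is fitted by total
  least squares through the five brow landmarks; the "eyebrow" point of
  the elevation marker is the apex (middle) landmark, 19/24.
* **Surface** — the Shannon entropy of a skin patch after edge
  highlighting (forehead, glabellar and lateral-canthal wrinkle lines),
  or the entropy of the absolute difference of consecutive cheek patches
  (cheek raises and relaxations).  Entropy is a per-frame scalar over
  the whole region, not a local entropy map, because the marker consumes
  only its variability over time.

## Regions of interest and image operators

Region geometry is expressed in IED multiples and anchored on
landmarks, so it tracks the face through translation and scale:
forehead 1.6×0.8 IED centred on the brow-apex midline, 0.15 IED above
the apices; nose root 0.5 IED square between the medial brow ends;
lateral canthal 0.5 IED squares 0.35 IED lateral of the outer eye
corners; cheeks 0.7×0.9 IED rectangles 0.25 IED below the lower eyelid,
bounded medially by the nose wing.  Patches are resampled bilinearly to
a canonical 64×64 grid; frames where less than half of a region lies
inside the image are skipped for that region.

Fixed numerical choices (all config-overridable, none published for the
original operators, so they are declared rather than inferred):

* intensity: BT.601 luminance divided by the representable maximum
  (255 for 8-bit) — deliberately *not* per-frame min–max, so temporal
  contrast changes remain visible to the entropy;
* edges: 3×3 Sobel kernels, gradient magnitude rescaled by 1/4 so a
  unit step edge maps to ≈1;
* entropy: 64-bin fixed-range histogram, 0·log 0 ≡ 0, bounded by
  log₂64 = 6 bits.  Edge patches use the (0, 1) range.  The cheek
  *difference* histogram uses a fixed (0, 0.5) range: consecutive-frame
  differences at 25 fps are far smaller than the full intensity range
  (a full-range histogram collapses them into one bin and the marker
  goes blind), while a much finer range starts resolving sub-bin
  tracker-jitter flicker, which carries no expression information.

## Recording-quality gating

Frames in which any landmark is invalid form gaps.  Gaps of at most
1 s are retained and filled by per-landmark linear interpolation in
time; longer gaps split the recording into segments and are excluded,
as are leading/trailing invalid frames (no valid neighbour on one
side).  Per-frame series are pooled across segments; quantities defined
on consecutive frames (the cheek difference) never straddle a segment
boundary, so exclusions cannot fabricate motion.  The fill method is
not dictated by the gating rule itself; interpolation is the default
and a "drop frames" policy is available in the configuration.

## Synthetic cohorts

No recordings of the emulated kind are public, so the generator is a
first-class module.  It animates a neutral 68-point template (unit IED,
y down) with: Poisson-timed smooth bumps for eyebrow raises (0.30/s),
frowns (0.20/s), blinks (0.30/s, 80 ms width), smiles/cheek raises
(0.25/s); unit-SD band-limited 2–7 Hz (syllabic-rate) oscillation for
jaw, upper and lower lip; slow sinusoidal rigid head translation; white
landmark jitter; and whole-frame occlusion gaps (0.05 events/s,
0.2–1.6 s).  Severity s ∈ [0, 1] scales every region's motion and
texture modulation multiplicatively: effective amplitude =
base × (1 − s·weight_region).  Default reduction weights are mouth and
jaw 0.7, forehead and nose root 0.6, eyebrows and cheeks 0.5, eyes 0.4,
lateral canthal 0.2 — lower-face and wrinkle dynamics most affected and
the canthal region least, reflecting how weakly that region's reduction
is observable on video.  Controls have severity 0; patients draw
severity uniformly from [0.2, 0.8].

Frames are rendered procedurally in grayscale: smooth face shading, a
static granular skin texture, wrinkle stripes in the forehead/
glabellar/canthal regions whose contrast is
depth × (0.2 + 0.8·signal·factor) — a static wrinkle floor plus an
expression-driven part — and a cheek brightness bump following the
cheek-raise signal.  Rendering is deliberately low-fidelity: the
surface markers consume texture *dynamics*, and nothing downstream
depends on photorealism.  What the generator does **not** emulate:
lighting changes, 3-D pose rotation and perspective foreshortening,
hair/glasses occlusion of specific regions, tracker biases correlated
with expression, or asymmetric (lateralised) impairment.  Passing tests
therefore demonstrate the pipeline's internal correctness and
sensitivity, not field performance on real video.

Clinical covariates are generated from severity through a noisy linear
model matched to the emulated population's marginals (age 61 ± 12;
bradykinesia/rigidity 3 + 35·s ± 5; MDS-UPDRS III adds a PIGD and
offset term; caudate SBR 3.6 − 1.2·s ± 0.3; putamen SBR 2.1 − 1.1·s
± 0.2; perceptual rating ≈ round(3.2·s − 0.2)), so motor scores rise
and binding ratios fall with severity.  Per-subject randomness comes
from documented substreams `SeedSequence([seed, subject_index])`;
cohorts are bit-identical under the same seed, and changing an
amplitude rescales rather than re-randomises the motion (all drives are
drawn before scaling).

## Statistics

* **Normality gate**: one-sample Kolmogorov–Smirnov on the standardised
  sample, normal ⇔ p ≥ 0.05.  Estimating mean/SD from the sample makes
  this gate anti-conservative (it accepts normality too readily); the
  Lilliefors-corrected variant (Dallal–Wilkinson approximation) is a
  switch.  Zero variance is non-normal by convention.
* **Group differences**: one-way ANOVA when both groups pass the gate,
  Kruskal–Wallis otherwise (robust to outliers); two-sided p-values.
  The 19 sided comparisons (twelve markers, seven with left and right
  variants) use a Bonferroni-adjusted level α/19 = 0.0026 at α = 0.05.
  Group tests run on sided values; correlations use side averages.
* **Partial correlation**: Pearson correlation of OLS residuals after
  regressing both variables on age (with intercept); t = r·√((n−3)/(1−r²))
  on n − 3 df, two-sided; complete cases only, no imputation.
* **Abnormality cutoffs**: per side-averaged marker, the empirical 5%
  tail of the control distribution in the direction of impairment.
  Since every marker *decreases* with hypomimia, the operational cutoff
  is the 5th percentile of controls with values below it abnormal; a
  configuration switch selects the literal "above the 95th percentile"
  direction for quantities that increase with impairment.  A facial
  region counts as affected when any of its pooled markers is abnormal
  (mouth pools three markers, eyebrows three); regions whose markers
  are all missing are excluded from the 0–8 affected-area count.

## Classification

LOSO logistic regression with per-fold z-scoring computed from the
n − 1 training subjects (no leakage from the held-out subject), a weak
fixed L2 penalty (1e−4 per sample on standardised features) so the fit
stays defined under perfect separation — plain logistic regression is
the penalty→0 limit — and PD as the positive class.  AUC uses the
rank/Mann–Whitney formulation with midrank tie correction; accuracy,
sensitivity and specificity are evaluated at probability 0.5 (a
declared choice).  The exhaustive subset search scores all 2^k − 1
candidate subsets by LOSO accuracy with deterministic tie-breaks
(higher AUC, then smaller subset, then name order).  By default the
selection is non-nested — the reported metrics reuse the LOSO scores
that drove the selection, which is optimistic for generalisation; a
nested mode repeats the search inside each outer fold.  The prevalence
operating point is the smallest score threshold whose control
false-positive rate is *strictly* under the 5% bound (with 75 controls
that means at most 3 above threshold, i.e. 4%); prevalence is the
patient fraction above it.

## Problem sizes and numerical checks

The nominal recording is one minute at 25 fps, 1440×1080.  The test
suite and the acceptance script use shorter, lower-resolution renderings
(4–12 s, 120×90 to 320×240) — marker variability, severity monotonicity
and the operating-point logic are resolution- and duration-independent
constructions, and these sizes keep full-cohort simulations at desk
scale.  Severity monotonicity of the surface markers is verified with a
paired common-random-number design (the same simulated subject rendered
at two severities), which cancels Poisson event-count variance between
subjects and estimates the same population mean difference with far
greater precision than independent groups.  Sample-SD computations are
checked against a two-pass brute-force oracle at 1e−12; the AUC and
partial-correlation implementations are cross-checked against
independent library references in the test suite.

## Known limitations

* ROI extents and the edge/entropy operators are declared defaults, not
  recovered from any published parameterisation; absolute marker values
  are therefore not comparable across tools, only within a pipeline.
* The markers quantify variability only — no blink counting, no
  velocity/amplitude decomposition of individual movements.
* Sub-second gap interpolation slightly damps variability relative to a
  hypothetical fully tracked recording.
* The non-nested subset search reports optimistic metrics by
  construction; use the nested mode for honest generalisation figures.
* The synthetic generator's realism limits (listed above) mean field
  performance on real video must be established on real video.
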
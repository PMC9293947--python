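# hypomimia

Automated video-based quantification of **hypomimia** (facial
bradykinesia) — the reduction of spontaneous and deliberate facial
movement that is among the earliest motor signs of Parkinson's disease
(PD).  The package turns per-frame 68-point facial-landmark time series
(iBUG 300-W convention) and, optionally, the grayscale video frames into
twelve interpretable facial-dynamics markers, and provides the
cohort-level pipeline used to characterise hypomimia in an early-PD
population: group statistics, age-controlled partial correlations,
normative abnormality cutoffs, and leave-one-subject-out (LOSO) logistic
classification with marker-subset search and a bounded-false-positive
prevalence estimate.

It is written for movement-disorder researchers who already have a
landmark tracker (the tracker itself is out of scope — any detector
emitting 68 iBUG points per frame can feed the pipeline) and want
reproducible, auditable marker extraction and statistics.

## The markers

Every marker is the sample standard deviation over time of one scalar
facial quantity — hypomimia *reduces movement variability*, so all
twelve are expected to decrease with disease severity.  Euclidean
distances are normalised per frame by the inner-eye-corner distance
(IED, landmarks 39–42), areas by IED², making the markers invariant to
face scale and camera distance.

| region          | marker(s)                                   | per-frame quantity |
|-----------------|---------------------------------------------|--------------------|
| forehead        | forehead_lines                              | entropy of edge-highlighted patch |
| nose root       | nose_root_lines                             | entropy of edge-highlighted patch |
| eyebrows (L/R)  | eyebrow_elevation, eyebrow_tilt, eyebrow_shape | ‖apex−nose tip‖/IED; brow-line angle; apex angle |
| eyes (L/R)      | palpebral_aperture                          | eye-contour shoelace area / IED² |
| lateral canthal (L/R) | lateral_canthal_lines                 | entropy of edge-highlighted patch |
| cheeks (L/R)    | cheek_surface                               | entropy of consecutive-frame difference |
| mouth           | upper_lip, lower_lip, mouth_corner (L/R)    | ‖landmark−nose tip‖/IED |
| jaw             | jaw                                         | ‖chin−nose tip‖/IED |

Seven markers have left/right variants (19 sided values); sides are
averaged for correlation and classification analyses.  Frames in which
any landmark is obscured form gaps: gaps of at most one second are
bridged by linear interpolation, longer gaps split the recording and are
excluded, so dropouts can never fabricate motion.

Because no recordings of this kind are publicly available, the package
ships a first-class synthetic generator (`hypomimia.synth`) that
animates a neutral face template with blink, eyebrow, smile and 2–7 Hz
speech-like dynamics, renders procedural grayscale frames with
expression-modulated wrinkle textures, and builds whole cohorts with
known ground-truth severity and clinically plausible covariates.

## Worked example

```python
import numpy as np, pandas as pd
from hypomimia import (SyntheticCohortConfig, simulate_cohort,
                       compute_marker_vector, loso_scores, roc_metrics,
                       prevalence_at_fpr, averaged_marker_names)

config = SyntheticCohortConfig(n_controls=20, n_patients=20, duration=8.0,
                               width=160, height=120, ied_px=17.0, seed=7)
cohort = simulate_cohort(config)

rows, y = [], []
for sid, seq in cohort.recordings.items():
    mv = compute_marker_vector(seq, cohort.frame_source(sid))
    rows.append(mv.averaged)
    y.append(1 if sid.startswith("PD") else 0)
X, y = pd.DataFrame(rows), np.array(y)

scores = loso_scores(X, y, subset=averaged_marker_names())
print({k: round(v, 3) for k, v in roc_metrics(scores, y).items()})
thr, prev, fpr = prevalence_at_fpr(scores, y, fpr_bound=0.05)
print(f"prevalence {prev:.2f} at control FPR {fpr:.3f}")
```

prints

```
{'auc': 0.995, 'accuracy': 0.975, 'sensitivity': 1.0, 'specificity': 0.95}
prevalence 0.90 at control FPR 0.000
```

AUC 0.995 means near-perfect PD/control ranking of this strong-effect
toy cohort; the prevalence line says 90% of simulated patients score
above a threshold that misclassifies none of the 20 controls (an FPR of
0 is forced here: with 20 controls, even one false positive would be
5%, not strictly under it).

The same pipeline is available from the shell:

```
hypomimia simulate --out sim --n-controls 20 --n-patients 20 --duration 8
hypomimia extract  --landmarks sim/landmarks --out markers.csv
hypomimia analyze  --markers markers.csv --cohort sim/cohort.csv --out analysis
hypomimia classify --markers markers.csv --cohort sim/cohort.csv --out clf
```

## Layout

- `hypomimia.io` — landmark/cohort file formats, gap gating, frame sources
- `hypomimia.roi` — facial regions of interest, luminance normalisation, edge highlighting, patch entropy
- `hypomimia.markers` — the twelve markers and the per-recording marker vector
- `hypomimia.synth` — synthetic recordings, rendered frames, cohorts with ground truth
- `hypomimia.stats` — normality-gated group tests, Bonferroni, partial correlations, normative cutoffs (`ControlPercentileCutoff`)
- `hypomimia.classify` — LOSO logistic screen (`LosoLogisticScreen`), subset search (`MarkerSubsetSelector`), ROC metrics, prevalence at bounded FPR
- `hypomimia.cli` — the `hypomimia` command

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
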
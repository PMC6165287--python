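# Methods

## The measurement problem

A single fixed 2-D camera filming a person walking past in profile yields,
after background subtraction, a sequence of binary silhouettes. gaitsil
turns one such walking pass into twelve biomechanical features and a
four-way gait classification: normal gait (NM), full-body movement
restriction (FB, the slow short-stepped hunched pattern typical of
parkinsonian gait), and right- or left-leg restriction (RL/LL, typical of
hemiplegic gait). The input contract is deliberately minimal — ordered
binary masks, a frame rate, and the configuration fact of which body side
faces the camera — so any background-subtraction front end can feed it.

## Pre-processing

Every silhouette is rescaled so its bounding box is `H = 200` px tall
(aspect preserved), with the box bottom on a common baseline row and the
horizontal trajectory carried through each frame's own scale factor. Height
normalization removes subject-to-camera distance as a nuisance variable;
all pixel-valued features are therefore reported in normalized pixels, not
metric units. `H = 200` keeps the bottom-10% feet band 20 rows tall, enough
for a stable Otsu threshold on the average feet image. Empty frames
(segmentation dropouts) are excluded; more than 20% empties aborts the
sequence. Normalization is idempotent: renormalizing a normalized sequence
is pixel-identical.

## Gait events from the feet-distance signal

The width of the silhouette's bounding box approximates the distance
between the feet: it peaks when the feet are spread at heel strike and dips
as they pass each other. The width signal is smoothed by a centered moving
average of `round(fps/6)` frames (5 at 30 fps), and:

* **initial contacts** are its local maxima, requiring prominence >= 5 px
  and separation >= 0.25 s (a human half cycle is at least that long even
  in fast gait);
* **mid-stance/mid-swing instants** are the single minimum strictly between
  each pair of consecutive contacts (plateau ties resolve to the earliest
  frame, for determinism).

Contact-delimited half cycles `[IC_i, IC_{i+1})` drive the feet features;
midpoint-delimited half cycles drive the amount-of-movement feature, since
they bracket the transfer of body weight from one side to the other. The
sequence duration `d` is the time between the first and last contacts.

## Feet features

**Average feet image (AFI).** Within one contact-delimited half cycle the
bottom 10% of rows of each frame (the anatomical feet band) are averaged
pixelwise. The stationary, flat foot accumulates intensity near 1; the
swinging foot smears out. An Otsu threshold — computed over the AFI's
nonzero values only, so the background zeros cannot dominate the
256-bin histogram — isolates bright pixels, and the largest 8-connected
component is the foot-flat footprint. Its unweighted centroid anchors all
step measurements. Uniform or empty AFIs skip the half cycle with a
warning rather than aborting.

**Left/right labelling.** Without depth, the foot farther from the camera
appears a few pixels more elevated (smaller image y). Each consecutive
footprint pair votes on the alternation parity via centroid y; the majority
fixes it, the near foot maps to the configured `camera_side`, and ties
within a pair abstain.

**Step lengths.** Step *i* is the Euclidean distance between centroids of
footprints *i* and *i+1*, assigned to the side of the arriving foot. Per
side, the median over the pass is reported (robust to a single bad half
cycle), and `SL_symm` is the absolute difference of the side medians.

**Normalized step count and speed.** `C = k / sum(SL)` (footprints per
pixel travelled) and `S = sum(SL) / d` (px/s). Because the summed steps
span one half cycle fewer than `d`, both estimators carry a small-sample
bias of order `1/(k-1)`; it vanishes for long passes, which is why the
parameter-recovery checks use 16-step walks while the cohort uses 6-step
passes.

**Foot-flat ratio.** Per footprint, frame-wise coverage is the fraction of
footprint pixels inside the silhouette. Frames with coverage >= 0.95 count
as flat foot ("complete contact", with a 5% segmentation-noise allowance);
the stance phase runs from the footprint's initial contact to the last
frame with coverage >= 0.5, a toe-off proxy (the sliding threshold choice
is the main free parameter of this feature; both are in the config). The
search window ends at the same foot's next contact so a later pass of the
other foot cannot extend the stance. `FFR = flat/stance`, clipped to
[0, 1]; per side, the median over footprints.

## Body features

**Gait energy image (GEI).** Frames of an interval are cropped to their
silhouette bounding box and averaged on a common canvas, bottom row on the
baseline and the silhouette's horizontal centroid on a common column. The
centroid (rather than box-center) alignment is the classic GEI convention:
the mostly static trunk stays crisp while moving limbs blur, so downstream
texture measures respond to limb motion rather than to box-geometry
jitter. Half-cycle GEIs use midpoint-delimited intervals; full-cycle GEIs
span `[IC_i, IC_{i+2})`.

**Amount of movement (AOM).** The half-cycle GEI is quantized to 256
levels; within its silhouette bounding box every horizontal right-neighbor
pixel pair contributes its difference to a histogram, and AOM is that
histogram's Shannon entropy in bits. A static (binary) GEI concentrates
differences on few values — low entropy; a moving limb spreads them. Each
mid-delimited half cycle takes the side of the foot whose initial contact
falls inside it; per-side medians and their absolute difference
(`AOM_symm`) are reported. Horizontal adjacency and the 256-level depth are
config knobs; both choices are deterministic and direction-consistent.

**COG shift.** On each full-cycle GEI, the center of gravity is the
intensity-weighted centroid of the whole image and the center of support
the intensity-weighted centroid of its bottom-10% feet band;
`COG_shift = |COG_x - COS_x|`, median over cycles. Note that even a
symmetric gait yields a nonzero shift of several pixels: the bright
flat-foot dwell happens early in stance, when the planted foot is ahead of
the body, biasing the feet-band centroid forward. The feature is therefore
an *index* of postural lean — monotone in commanded torso lean, and
markedly larger for hunched gait — not a calibrated displacement.

**Torso orientation (TO).** The torso band of the full-cycle GEI (rows
between 13% and 47% of the silhouette height from the top, standard
anatomy ratios for neck and hip; configurable) is summarized by the
intensity-weighted covariance of its pixel coordinates. TO is the angle
between the horizontal axis and the leading eigenvector, folded into
[0, 90] degrees by taking absolute components. Upright walkers score near
90; a 25-degree forward lean scores near 65.

## Screening and classification

Each of the twelve features is screened with Welch's unequal-variance
two-sample t-test (alpha = 0.05) against the normal-gait group, one
impaired group at a time; the implementation computes the statistic and
Welch–Satterthwaite degrees of freedom in closed form and uses the t
distribution only for the tail mass. Degenerate (constant) features are
excluded with a warning.

Classification uses a support vector machine with a quadratic kernel —
implemented as a degree-2 polynomial kernel with `coef0 = 1`, `C = 1`,
one-vs-one multiclass — after z-scoring each feature with training-set
statistics (the features span three orders of magnitude; unscaled
polynomial kernels degenerate). A linear-kernel mode exists for
comparison. Evaluation is subject-exclusive fivefold cross-validation:
sorted subject identifiers are shuffled by a seeded generator and chunked
into folds, so all sequences of a subject live in exactly one fold and no
individual ever appears on both sides of a split (asserted as a hard
invariant). Reported outputs are per-fold accuracies, their mean, the
pooled confusion matrix (class order FB, RL, LL, NM), per-class and macro
recall/precision, and the goodness index
`G = sqrt((1 - macro recall)^2 + (1 - macro precision)^2)`, which is 0 for
a perfect classifier.

## The synthetic walker

Because the reference recordings are not redistributable, the package
ships a fully ground-truthed generator. It renders a lateral-view body —
head ellipse, leanable torso, two-segment legs with a forward knee bow,
flat rectangular feet — advancing through a commanded contact schedule:

* feet plant at commanded positions (per-side step lengths), dwell
  flat-footed for `flat_fraction` of a stance lasting 60% of the gait
  cycle, roll slowly about the toe to 20 degrees by lift, and swing to the
  next contact along a back-loaded arc with a plantar-flexed mid-swing
  tuck;
* per-side `movement_scale` in (0, 1] scales the swing arc and knee
  flexion, and below 1 compresses the arc into the early swing followed by
  a near-ground glide — a hesitant, low-clearance shuffle;
* the torso leans by `torso_lean` degrees; the hip advances piecewise
  linearly between contacts; after the last commanded contact the trailing
  foot begins a closing swing so the final heel strike is a genuine width
  maximum;
* the far-side foot is drawn a few pixels taller on the shared ground
  line, reproducing the elevation cue of real lateral views while keeping
  the silhouette baseline (and hence the per-frame normalization) stable;
* the leg joins the foot above its center so the in-band shank strip does
  not bias footprint centroids along the walking direction.

Class presets: NM (108 px steps, 0.9 steps/s, upright, unrestricted,
flat fraction 0.6), FB (40 px steps, 0.75 steps/s, 25-degree lean, both
movement scales 0.5, flat fraction 0.8), RL (right step 55 px vs left
100 px, right movement scale 0.55), LL mirrored. The NM step length was
set so the normalized step count lands near 0.010 steps/px at 6 contacts
per pass, and FB near 0.025 — the step-density regime of the reference
recordings. Cohorts draw 10 subjects x 2 sequences x 4 classes at 30 fps,
with seeded 5% multiplicative "subject" jitter on all parameters shared by
a subject's two recordings and 2% within-subject jitter between repeats.
An optional pixel-flip noise flag emulates segmentation noise.

**What the generator does and does not emulate.** It reproduces the
silhouette phenomena the pipeline consumes — width periodicity, foot
dwell and roll-over, step asymmetry, lean, limb-excursion asymmetry, the
far-foot elevation cue — with schematic sinusoidal-phase kinematics, no
arms, no clothing or segmentation artifacts beyond optional pixel flips,
and perfectly repeatable geometry. Passing tests on it therefore
demonstrate that the pipeline measures what the generator commands, not
that real silhouettes are this clean; in particular the absolute entropy
(AOM) values of the schematic walker are lower than those of real
recordings, and left/right AOM contrasts are small though consistently
signed.

## Numerical choices and degenerate inputs

* Grayscale inputs binarize as "nonzero is foreground"; rescaled masks
  re-binarize at 0.5.
* Otsu ties between equal-variance cuts take the lowest threshold; the
  test oracle checks achievement of the exhaustive between-class-variance
  maximum, since spiky histograms make the argmax plateau
  floating-point-arbitrary.
* Plateau minima in midpoint detection take the earliest frame.
* Zero-variance Welch inputs: equal means give p = 1, distinct means
  p = 0; samples smaller than 2 are errors.
* Fewer than 2 detected contacts, a missing side, an empty feet band, or a
  single-pixel torso band raise typed errors rather than propagating NaNs.
* All randomness (presets, cohorts, noise) flows through seeded NumPy
  generators; fixed seeds give bit-identical silhouettes.

## Problem sizes

Cohort evaluations use 6 commanded steps per sequence (about 190 frames at
30 fps) and 80 sequences per cohort; parameter-recovery checks use 16-step
walks, where the `1/(k-1)` small-sample bias of the speed and step-density
estimators is below the 10% recovery tolerance. These sizes are the
package's default study conditions; longer passes only tighten the
estimates.

## Known limitations

* Features are in normalized pixels; no metric calibration is attempted.
* The toe-off proxy (coverage falling below 0.5) has no independent
  ground-truth validation beyond the synthetic walker.
* The COG-shift feature carries the stance-dwell forward bias discussed
  above and is best read comparatively.
* Single-person, lateral-view scenes only; background subtraction is out
  of scope (a helper binarizes grayscale masks, nothing more).
* The quadratic-kernel hyperparameters (`coef0`, `C`) follow common
  defaults; no hyperparameter search is performed, matching the intended
  use as a fixed measurement instrument.
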
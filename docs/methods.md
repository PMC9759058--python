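# Methods

## Input model and assumptions

The pipeline assumes a two-channel acquisition exported as two directories of
numbered single-channel 8-bit frames: an interstitial channel (fluorescent
dextran labels the interstitium; alveolar airspaces are dark) and a
neutrophil channel (labeled leukocytes are bright blobs on a dark
background). Frames are ordered by the first integer run in each filename,
because raw microscopy exports commonly use unpadded counters. 16-bit
sources are linearly rescaled to 8-bit (max-value mapping) behind an
explicit flag. Channel compositing assigns interstitium to blue and
neutrophils to red, with green reserved all-zero, so the composite is
losslessly invertible.

The input is assumed reasonably clean: illumination-field correction, motion
registration, and recovery from sudden image-quality collapse are out of
scope.

## Preprocessing

Two denoising stages per channel:

1. **Non-local means** over the whole frame. Defaults: filter strength
   h = 35 (interstitial) / 45 (neutrophil), template window 7 px, search
   window 21 px. The implementation uses scikit-image's fast NLM with
   `patch_size = template` and `patch_distance = (search − 1)/2 = 10`, with
   h on the 0–255 intensity scale; h = 0 is the identity.
2. **Mask formation**: Gaussian blur (kernel 11; σ from the conventional
   σ = 0.3·((k−1)/2 − 1) + 0.8 rule, here 2.0) → intensity threshold →
   square dilation (side 4). The order blur → threshold → dilate is fixed
   and documented. Alveoli are segmented as *dark* regions of the
   interstitial channel (threshold default 50, pixels below kept);
   neutrophils as *bright* regions of theirs (default 60, pixels above
   kept). The cutoffs are exposed hyperparameters since only the blur and
   dilate kernel sizes are canonical.

Interstitial area itself is measured from a bright-polarity mask of the
interstitial channel using the same parameters (polarity flipped); with the
default threshold of 50 this counts essentially all dextran-labeled tissue.

Every preprocessing operation is deterministic and dimension-preserving.

## Segmentation

Feature contours are the external boundaries of 8-connected foreground
components of the mask (sub-pixel boundary via marching squares at level
0.5 with high connectivity, so diagonal components stay on one ring).
Component pixel count — not polygon area — is the feature area; the centroid
is the mean of the component's pixel coordinates. Holes inside components
are ignored. Boundary tracing of components is used as the concrete,
reproducible realization of edge-detection-based contour extraction; the
result is equivalent for binary masks, and agreement with an independent
flood-fill labeling is asserted in the test suite.

Area restrictions (defaults at 512×512 scale: alveoli 200–26 000 px²,
neutrophils 30–800 px²) are exposed per-channel hyperparameters sized to
typical feature scales; they are a pure, idempotent interval filter.
Coordinates are 0-based with x = column, y = row.

## Temporal-consistency filter

A detection at frame *t* is valid iff it matches at least one detection of
the *unfiltered* neighbor frames *t−1* or *t+1* (first/last frames check
their single neighbor). A match requires **both** centroid proximity and
area agreement:

- centroid distance ≤ `centroid_radius` (defaults 20 px alveoli, 15 px
  neutrophils) — area matching alone would conflate distant same-sized
  features, so a spatial gate is imposed;
- areas within `area_tolerance_rel = 0.5` of the larger area for alveoli
  (breathing deformation is large) or within `area_tolerance_abs = 50 px²`
  for neutrophils.

Matching is existential, not one-to-one assignment. Because the match
predicate is symmetric, a feature removed for lacking neighbors can never
have been another feature's only validator, so the single pass already
reaches the filter's fixed point (asserted as an idempotence test). Rejected
detections are logged (frame, centroid, area, reason). A greedy
nearest-centroid track linker is provided as a clearly-labeled extension
beyond the validity filter.

## Per-frame features and respiratory cycles

Per frame: alveolar area % of image area, alveolus count, airspace per
alveolus (alveolar % / per-frame count), neutrophil count and area %, and
interstitial area %. Percentages are normalized by total image area; counts
use the post-filter detections.

Cycle detection smooths the alveolar-area signal with a centered moving
average (window 3) and finds troughs — local minima with prominence
≥ 0.5 percentage points and ≥ `min_cycle_len` = 4 frames separation — via
`scipy.signal.find_peaks` on the negated signal. Cycle *k* spans
[trough_k, trough_{k+1}); troughs anchor cycles at end-expiration so each
cycle rises through inspiration and falls back, matching ventilator
volume–time curves. Min/max per cycle come from the *unsmoothed* signal
within the span; frames outside the first/last trough belong to no cycle,
and consecutive cycles tile the covered range exactly. A constant signal
has no troughs and raises "no complete respiratory cycle detected".

Experiment summaries (radar-chart axes) are the means of alveolar area %,
per-cycle amplitude (max − min), alveolus count, neutrophil count,
neutrophil area %, and cycle length; axes are min-max normalized to [0, 1]
across the loaded experiments for shape comparison, with amplitude/length
reported absent when no cycle exists.

## Two-experiment comparison

Series B is aligned by a user-supplied integer frame offset (dropping
leading frames for positive offsets, trailing for negative; no resampling),
with an optional automatic offset maximizing the cross-correlation of the
two alveolar-area signals as a labeled extension. The per-cycle scalar is
the *mean* of the per-frame feature over the cycle — the stable choice when
no canonical per-cycle statistic exists. Outputs: slope pairs (first-cycle
mean, last-cycle mean) per feature and experiment; min/q25/median/q75/max/
mean distribution summaries (linear-interpolation quantiles) plus raw
per-frame values so any plotting layer can draw violins; and the per-cycle
absolute difference |mean_A(k) − mean_B(k)| for k up to the smaller cycle
count (symmetric in the two series). Neutrophil area is compared as % of
image area for scale invariance. No hypothesis testing is performed.

## Synthetic scenes

The generator emulates the structure of the real data, not its texture:

- interstitial channel: uniform bright background (200) with dark (10)
  filled ellipses whose radii scale by s(t) = 1 + A·sin(2πt/P);
- neutrophil channel: dark background (20) with bright Gaussian-profile
  blobs (peak 210, σ = radius/2) drifting on straight reflected tracks,
  plus single-frame transient blobs;
- additive Gaussian sensor noise, clipped to [0, 255].

Benchmark defaults: 256×256 px, 64 frames, period P = 16, amplitude
A = 0.25, 6 alveoli of radius 12–18 px, 5 neutrophils of radius 4–6 px
drifting 1 px/frame, 20 transients, noise σ = 5 — sized so features are
well-resolved at desk scale while the 64-frame video still spans 3 complete
breaths and finishes each pipeline stage in seconds on one core. Breathing
modulates radii, not positions, so centroids stay within the tracking
radius. Alveoli are placed with pairwise center distances exceeding the sum
of their peak-inflation radii; neutrophil tracks are rejection-sampled until
no two blobs ever come close enough to merge; transients are kept ≥ 30 px
(twice the neutrophil tracking radius) from every persistent neutrophil and
from transients in adjacent frames, so their removal is unambiguous.
Ground truth records the analytic area π·a·b·s(t)² and centroid of every
feature in every frame; rasterized pixel counts track the analytic areas to
within ~3% at these radii. Identical configs (including seed) produce
bit-identical frames.

What the generator does **not** emulate: Poisson shot noise (additive
Gaussian only, for determinism of the expected contrast), respiratory-motion
blur, focal drift, vessel/texture background structure, neutrophil
appearance/disappearance, and image-quality collapse. Passing recovery
tests therefore demonstrates the pipeline's correctness and its behavior
under the modeled degradations, not segmentation accuracy on arbitrary real
recordings — on real data the exposed thresholds and area restrictions are
expected to need tuning.

## Numerical choices and degenerate inputs

- Thresholds are strict inequalities; the dark-feature mask is monotone in
  the threshold before dilation.
- Even dilation kernels use scipy's centered square structuring element
  (asymmetric by one pixel, as is conventional).
- Quantiles use linear interpolation; Gaussian blur uses nearest-edge
  padding.
- Empty masks segment to empty contour lists; frames with no alveoli report
  zero alveolar area and zero airspace-per-alveolus; the temporal filter
  requires ≥ 2 frames; cycle detection requires ≥ 2·min_cycle_len frames
  and ≥ 2 troughs.
- All stages are deterministic; the only randomness in the package is the
  seeded scene generator.

## Known limitations

Merged adjacent alveoli are not split (no watershed); nested dark regions
are treated as holes and ignored; the temporal filter validates existence
but does not form identities (the track linker extension is greedy and can
switch labels on crossing paths); automatic offset estimation can lock onto
any integer multiple of the breathing period; only two experiments are
compared at a time.
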
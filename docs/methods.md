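# Methods

## The picking algorithm

A sliding-window particle scorer assigns every position of a down-sampled
micrograph a figure-of-merit (FOM). For globular particles, coordinates are
extracted from this image by non-maximum suppression; for filaments that
step is replaced by a line-extraction stage with four operations
(`helipick.trace_extraction`):

1. **Binarization.** `mask = FOM > t`, strictly greater, at the
   user-supplied threshold `t`. The useful range depends on the scorer: for
   neural-network logits it is typically −4 to −7; for the surrogate scorer
   shipped here the score is expressed in units of the image's pixel noise
   and the default threshold is 1.1 (see below).
2. **Skeletonization.** The mask is thinned to one-pixel-wide, 8-connected
   medial lines (scikit-image `skeletonize`, Zhang–Suen-style iterative
   thinning). The skeleton is a subset of the mask, preserves component
   connectivity, and is a fixed point of re-thinning — all three are tested.
3. **Line detection.** A probabilistic Hough transform
   (scikit-image `probabilistic_hough_line`) with minimum line length
   `fl = 2r` (twice the picking radius `r`), accumulator threshold
   `max(1, round(0.1 fl))` and maximum bridged gap `r`. The angle
   accumulator is sampled at 1° steps over [−90°, 90°); candidate pixels
   are visited in a pseudo-random order fixed by a seed, so the output is
   reproducible.
4. **Merging.** Two segments merge when (a) the undirected angle between
   them is below 10° and (b) at least two of the pair's four endpoints each
   lie within `r` of the *other* segment's infinite supporting line.
   Distance is measured to the infinite line, not the finite segment —
   the reading under which collinear-but-gapped fragments (the situation
   merging exists for) are mergeable. Scanning is deterministic: repeated
   passes over pairs in index order, restarting after every accepted merge,
   until a pass accepts none.

The radius `r` is half the particle diameter divided by the down-sampled
pixel size, floored at one pixel; the diameter should reflect the average
filament width (120 Å is a good default for tau-like fibrils).

**Merged-segment construction.** A merged segment remembers its original
constituents. Its axis is the length-weighted principal axis (total
least-squares line) of the constituent endpoints through their weighted
centroid; the two extremal endpoint projections onto that axis become the
new endpoints. Fitting endpoint *positions* was chosen over averaging
segment *directions*: a short, slightly tilted end fragment leaves the
positions on the true line but would rotate a direction average by ~1°,
which at the end of a long merged line is several pixels of perpendicular
error. Because the construction depends only on the constituent *set*, the
result is independent of the order in which pairs were merged.

**Non-confluence.** The merge relation is not confluent in rare borderline
configurations: in roughly 1 % of random ≤5-segment instances, different
merge orders reach different fixed points (a pair that merges may produce a
segment that no longer meets the criterion with a third, and vice versa).
The deterministic index-order schedule picks one reachable fixed point; the
test suite verifies against an exhaustive all-orders oracle that the result
is always in the reachable set and equals the oracle exactly whenever the
fixed point is unique.

**Coordinates.** All pixel coordinates are 0-based, pixel-centre; x is the
column, y the row (down). Down-sampled → micrograph rescaling is centre-
preserving under block averaging: `x_mic = (x_ds + 0.5) f − 0.5`.
Zero-length segments, if the Hough stage emits any, are dropped.

## Helical bookkeeping

A twisted filament completes a half-turn over its crossover distance `d`
(the period of apparent-width alternation in projection), so the twist per
asymmetric unit of rise 4.75 Å is `−(4.75 × 180)/d` degrees — negative by
the left-handed convention of most amyloids (720 Å → −1.19°, 750 Å →
−1.14°, 855 Å → −1.0 exactly). Segments are extracted every
`rise × n_asu` Å along each trace (14.25 Å for three β-rungs), each record
carrying the trace's in-plane angle as its psi prior, a tilt prior of 90°
(filaments lie in the image plane) and its arc distance from the trace
start as the helical track length. The psi convention is
`psi = −atan2(Δy, Δx)` in degrees wrapped to (−180°, 180°], with image y
downwards; for a curved filament picked as several straight traces, track
length restarts at each trace (each has its own tube id). A refined rise
`h` differing from 4.75 Å is attributed entirely to pixel-size
miscalibration: the corrected pixel size is `nominal × 4.75 / h`.

## File formats

Pick files are single-`loop_` STAR tables of `_rlnCoordinateX/Y` with
consecutive row pairs forming one filament's (start, end); particle files
carry the minimal helical-prior column set (micrograph name, x, y, tube id,
tilt prior, psi prior, track length in Å). Coordinates are written 0-based
pixel-centre in original-micrograph pixels with six decimals; writers and
readers round-trip at that precision. MRC I/O follows MRC2014 (modes
0/1/2/6) via `mrcfile`, with explicit, distinct errors for malformed
headers, unsupported modes and truncated data.

## The synthetic micrograph generator

The simulator (`helipick.synthetic`) exists to make the pipeline testable
with exact ground truth; its defaults are the package's standard study
conditions. A micrograph is a 1024 × 1024 field at 2 Å/px (2048 Å across)
containing five filaments, each a constant-curvature arc (|curvature| ≤
0.01 rad per 100 Å of arc) of finite length drawn between 2 and 4.5
crossover distances, rendered as a dark ridge of Gaussian cross-profile on
a zero background with additive Gaussian pixel noise applied last.
Filament placement applies steric exclusion — candidates running along an
existing filament (more than 15 % of their length within one maximal width)
are redrawn — because filaments in a thin ice layer cannot co-localise;
steep crossings remain. Everything derives from one seed; output is
bit-reproducible.

Apparent width and contrast are coupled through a projection-thickness law.
The cross-section of a twisted fibril is anisotropic, so its apparent width
`w(s)` oscillates between `w_min` = 70 Å and `w_max` = 140 Å with arc
period `crossover/2` (a 2-fold projected cross-section repeats its width
twice per full turn), while the beam path through it varies inversely:
rendered depth is `contrast × w_min / w(s)`. Narrow projections are dark,
wide crossover regions pale — the alternating strong/weak signal that makes
a low picking threshold necessary on real data. The damage phenotypes:

- **swollen** — the width is a smooth random field (150 Å correlation
  length, log-normal-like excursions from 0.5 w_min to 2.5 w_max) under the
  same depth law: blobby shapes with erratic contrast;
- **ribbon** — constant width and uniformly pale (0.15 × contrast): a
  non-twisting flat ribbon is a sheet of laterally packed protofilaments
  (~20 Å thick against ~140 Å wide) lying flat in the ice, so the beam
  always traverses its thin dimension.

What the generator does *not* emulate: CTF oscillations and defocus
gradients, radiation damage, ice-thickness gradients, carbon edges, surface
contamination, and true 3-D helical density projection. Passing tests
therefore demonstrate the correctness and robustness of the extraction
geometry under controlled contrast and noise, not performance on any real
data set.

## The surrogate scorer

The sliding-window neural-network scorer is external to this package; its
stand-in (`surrogate_score_map`) is an oriented matched-filter bank. The
micrograph is block-averaged (factor 4 by default), then convolved at 36
orientations with an anisotropic difference-of-Gaussians ridge kernel:
FWHM equal to the expected filament width across the axis (minus a 3×
wider Gaussian as local background estimate) and 1.75× elongated along it.
The strongest response over orientations is sign-flipped so filaments score
high. Axial elongation is what carries the weak, wide crossover sections —
the same role context plays for a sliding-window classifier — and the image
is padded with its median before the rotations so that edge streaks are not
mistaken for ridges.

Scores are expressed in units of the down-sampled image's pixel noise,
estimated robustly from first differences (filament structure is smooth at
the one-pixel scale and cancels). Image-content statistics are deliberately
not used for scaling: normalising by a whole-image variance would rescale a
field of weak objects (e.g. ribbons) up to look like strong filaments. The
scale is floored at half the peak response so the noiseless limit behaves
continuously; a constant image yields an all-zero map. On this scale,
background fluctuations stay below ~0.1, healthy filaments score above ~1
even in their pale sections, and ribbons sit around 0.2–0.5; the default
threshold is 1.1. Like any picking threshold it should be tuned per data
set — the five-panel diagnostic (`--fp`) exists for exactly that.

## Pick evaluation

`evaluate_picks` scores traces against ground-truth centrelines. A trace is
a true positive when both endpoints lie within the distance tolerance of
the *same* truth polyline and its direction is within the angle tolerance
of the local polyline direction (a line merged across two distinct,
accidentally collinear filaments is counted as wrong: it extracts segments
from empty ice between them). Matching is greedy by decreasing trace
length, ties broken by tube id. Coverage is the length-weighted fraction of
truth arc within the distance tolerance of a true-positive trace;
`recall_by_length` is the fraction of filaments individually covered over
at least half their length. With no picked traces precision is 1 by
convention and coverage 0. The standard tolerances are the picking radius
(in micrograph pixels) and 10°.

Under the default study conditions (noise at half the filament contrast),
pooled over 20-seed micrograph sets, the default pipeline reaches ~0.91–0.96
coverage at ~0.92–0.97 precision depending on the seed base; swollen
filaments degrade coverage by ~0.15 and ribbons are not picked at all at
the default threshold. The known failure modes are filament crossings
(where the fused binary mask makes the skeleton cut corners — also a
failure mode of picking on real micrographs) and occasional merging of two
nearly collinear distinct filaments.

## Numerical choices and edge cases

- Binarization is strictly `>`; an all-false mask, an empty skeleton and an
  empty trace list are legal results at every stage.
- The Hough stage is the only randomised step; its seed is part of
  `PickerParams` and flows from the single `--seed` of the CLI.
- `radius_pixels` rounds half-to-even and floors at 1 px; human-readable
  reports round half-to-even at the printed precision while full precision
  is kept internally.
- Degenerate inputs raise `ValueError` with specific messages: zero-length
  traces, non-positive spacings and rises, tolerances ≤ 0, empty ground
  truth.
- The end-to-end fidelity test (noiseless, straight, constant-width,
  non-crossing filaments) bounds each recovered trace by one down-sampled
  pixel of perpendicular offset at its midpoint and 2° of direction error;
  offset and tilt are bounded separately because an endpoint bound
  conflates the two.

## Limitations

- Curved filaments are picked as multiple straight traces by design;
  there is no spline tracing, and track lengths restart per trace.
- The merge criterion has no along-line gap limit, so two accidentally
  collinear filaments can merge into one trace.
- The surrogate scorer is a linear filter bank: unlike a trained
  classifier it cannot learn to reject crossings, carbon edges or
  contamination, and its score scale is its own (thresholds do not
  transfer to network logits).
- Crossover-distance *measurement* from micrographs is out of scope; the
  conversion assumes `d` is supplied.
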
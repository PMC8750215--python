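# Methods

## Data model

All analysis operates on two tidy tables. A **track table** holds
time-ordered planar positions (µm) of moving EB1 comets — each comet marks
a growing microtubule plus-end — grouped by track id, together with the
acquisition frame interval (seconds). A **spot table** holds per-frame
positions and diameters of near-immobile membrane clusters grouped by spot
id. Frames are 0-based integers; the Imaris reader converts the 1-based
`Time` column on input and converts positions to µm using the per-row
`Unit` column. A `z` coordinate, when present, is parsed and carried but
all distances are planar: the analysis concerns the cell-cortex plane, and
the image distances the collision criterion is defined on are 2-D.
Diameters may come from a separate Imaris diameter-statistics file joined
on object id, or from a constant fallback.

## Collision criterion

Let *d* be the Euclidean distance between a comet center and a spot center
in one frame, *D* the spot diameter and *b* ≥ 0 the border allowance
(default 0.1 µm). The frame is a **contact** when

    d < D/2 + b            (border criterion, strict inequality)

i.e. the comet center comes within *b* of the spot border. Ties at
exactly *D*/2 + *b* are non-contacts. A legacy screening rule that
compared the center distance to the full diameter is kept as
`criterion="diameter"` for reproducibility of older analyses; it is
equivalent to the border rule with *b* = *D*/2. Spots not detected in a
frame contribute no contacts in that frame; spot positions are never
interpolated, because the clusters are observed to be laterally stable and
interpolation would invent data.

Contacts of one (track, spot) pair in consecutive frames (inter-frame gap
≤ `episode_gap`, default 0 — the most conservative reading of "one
collision") merge into one **episode**. The episode's anchor is the frame
of minimal border distance (first such frame on ties): downstream kinetics
need a single "collision time frame", and the closest approach is the
natural choice over, say, the episode's first frame.

The detector groups points by frame and evaluates a distance matrix per
frame; its output is tested for exact equality against a brute-force
all-pairs-all-frames oracle, and for invariance under rigid motions and
monotonicity in *b*.

## Track, spot and collision statistics

* per-step speed: step distance / (Δframe · frame interval), µm/s;
* whole-track mean speed: unweighted mean of step speeds (the per-step
  "Speed" convention of common tracking software);
* straightness: displacement / path length ∈ [0, 1]; defined as 0 for a
  degenerate zero-length path;
* spot maximal displacement: max over frames of the distance from the
  first observed position;
* near-collision speed: mean step speed over the frame window
  [anchor − 1, anchor + 3] by default, clipped to the track extent; only
  steps lying fully inside the window count, so the default window holds
  at most 4 steps. A window with no steps is an error for the single-
  episode call and a flagged row in batch kinetics.

A collision is **unaffected** when |near − whole| ≤ 0.05 · whole, else
**accelerated** or **decelerated** by sign. The 5% relative tolerance is
a free parameter: the class exists in the field's reporting but no
published tolerance defines it, so it is surfaced in the configuration and
CLI. Straightness is additionally computed on the sub-tracks up to and
from the anchor frame; a side with fewer than two points is reported as
undefined rather than failing, and "straightness decreased" compares the
after-side to the whole track.

Per cell, only tracks whose path length strictly exceeds 5 µm are
followed (short tracks carry little kinetic information and inflate
denominators). Percentages of colliding tracks and spots use all retained
tracks and all spots as denominators. For the class mix, each colliding
track is counted once with the majority class of its episodes, ties
breaking to the class of the episode with the smallest minimal border
distance (the most definite contact); the accelerated-with-straightness-
loss percentage uses the representative episode of the winning class.
Counting tracks rather than episodes, and the majority rule, are package
choices — per-track class percentages are the field's reporting unit but
multi-collision aggregation is not standardized; both per-episode kinetics
and per-track summaries are emitted so either convention can be derived.

## Orientation dispersion of fiber images

Local orientation is estimated from the structure tensor: gradients are
taken with Gaussian-derivative filters at scale 1 px (central differences
show an angle-dependent bias of several degrees on thin anti-aliased
lines), tensor products are integrated with a Gaussian of 2 px, and the
fiber angle is the tensor's minor eigenvector, measured from the image
x-axis with period 180°. Each pixel enters a histogram over [−90°, 90°)
(default bin width 2°) weighted by the tensor's eigenvalue difference, so
isotropic background contributes almost nothing.

The highest peak is summarized by a Gaussian fit. The histogram is
unwrapped around its mode so the peak never straddles the ±90° seam, then
regularized with a circular Gaussian kernel whose bandwidth equals the
circular standard deviation (clipped to [bin width, 30°]) — KDE-style
smoothing that suppresses the spikiness of histograms built from few
discrete structures, which otherwise makes a least-squares fit latch onto
the densest sub-cluster and underestimate the width by up to a third.
A four-parameter Gaussian (amplitude, center, σ, baseline) is then
fitted, and the kernel width is removed from the fitted σ in quadrature;
since a Gaussian convolved with a Gaussian is Gaussian, an exactly
Gaussian histogram is recovered exactly. Reported are the **dispersion**
(the deconvolved σ, degrees) and the **amount**: the mass of the *raw*
histogram within ±1 dispersion of the fitted center, fractional bins
pro-rated, divided by the total mass — ≈ 0.683 for a Gaussian
orientation distribution. Degenerate fits (flat histogram, vanishing
amplitude, σ at the 90° bound, R² < 0.2) raise a fit-failure error that
carries a fallback result (mode center, circular-std dispersion).

## Synthetic data: what it emulates and what it does not

Comet tracks are persistent random walks: one intrinsic speed per track
drawn from N(0.266, 0.152²) µm/s (negative draws rejected), heading
increments N(0, turn_sd²) per step, 50 frames at 1 s, starts uniform in a
30 µm field. The speed distribution matches measured EB1 comet speeds in
leaf epidermis; `turn_sd` defaults to 15°/step, which yields a mean track
straightness of ≈ 0.77 ± 0.16 at 50 frames, spanning the 0.7–0.85 range
measured for EB1 tracks. Spots are fixed anchors with independent
Gaussian jitter per frame (σ = 0.05 µm) — not a random walk, so the
maximal displacement stays bounded at the ≈ 0.18 µm scale observed for
membrane clusters — and diameters N(0.5, 0.1²) µm, floored at 0.1 µm.

Planted collisions center a spot exactly on the track position at a chosen
frame and rewrite the track from that frame per the outcome: *pass*
(continue, optionally speed-rescaled), *pause* (position held a few frames
then the track ends — a stalling comet disappears rather than waiting
forever), *detach_turn* (heading rotated, transient extra waviness),
*retract* (the tip retraces its own path backward, speed-rescaled).
Background spots are rejection-sampled at least diameter/2 + buffer +
3·jitter + 0.05 µm from every track point, so an empty plan guarantees
zero contacts. Plants on one track closer than the kinetics window are
rejected.

Fiber images are anti-aliased straight segments (length 0.6 × image side,
2 px wide) with angles from a wrapped normal, plus Gaussian pixel noise.

Not emulated: point-spread-function blur, photobleaching, detection
dropouts and linking errors, curved microtubules, spot appearance or
disappearance, and comet intensity profiles. Passing tests therefore
demonstrate correctness of the geometry, merging, kinetics and estimator
logic under clean tracking — not robustness to segmentation artifacts in
real movies.

## Numerical and design choices

* Strict `<` in the contact criterion; enlarging the buffer can only add
  contacts (tested superset property).
* All generators are reproducible from an integer seed
  (`numpy.random.default_rng`); equal seeds give byte-identical CSVs.
* Result CSVs write floats with 10 significant digits and round-trip
  exactly through the package readers.
* Whole-track speed of exactly 0 makes the speed class undefined
  (degenerate-track error); batch kinetics flag such episodes instead of
  aborting.
* Orientation estimator accuracy, measured on the synthetic fibers at
  512², 60 fibers, 5 seeds: mean peak error < 0.5° and mean dispersion
  within ~20% of truth for true spreads of 5–20°; per-image dispersion can
  deviate further because a single image carries only 60 drawn angles
  (sampling error of the mean alone is ±2.6° at a 20° spread).
* Animation: world-to-pixel scale from the data bounding box plus 5%
  margin; the collided (white) state is sticky from the first episode
  frame; annotations are drawn gray so pure white is unambiguous.

## Known limitations

* The per-cell summary assumes one field of view per call; cross-cell
  statistics (tests, ANOVA) are out of scope — the summary CSVs are the
  hand-off point.
* Orientation analysis fits a single peak; strongly bimodal arrays are
  reported by their dominant mode only, with the secondary mode visible
  only through a lower amount and fit quality.
* MP4 export requires an ffmpeg-enabled imageio backend; GIF export has
  no external dependency.
* Tracks touching two overlapping spots in one frame yield two contacts
  and two episodes; no deduplication is attempted.
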